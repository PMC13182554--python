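"""Molecular representations: RDKit descriptor vectors, fingerprint families, Tanimoto.

All encoders are deterministic functions of the canonical SMILES. Fingerprints
are exposed both as sklearn-style transformers and as thin module functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

RDLogger.DisableLog("rdApp.*")

ENCODERS = (
    "descriptors",
    "morgan_bits",
    "morgan_counts",
    "maccs",
    "path_fp",
    "torsion_fp",
    "atompair_fp",
)

#: defaults follow the similarity setting used for leakage grouping
MORGAN_RADIUS = 3
MORGAN_NBITS = 2048
MACCS_NBITS = 167


@dataclass
class FeatureMatrix:
    """An n x d numeric feature matrix with provenance metadata."""

    values: np.ndarray
    feature_names: list[str]
    encoder_id: str
    encoder_params: dict
    row_keys: list[str]
    errors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_keys), len(self.feature_names)):
            raise ValueError("shape does not match row_keys/feature_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_keys, columns=self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


@dataclass
class Fingerprint:
    """Sparse fingerprint: set-bit indices (bit form) or index->count map."""

    n_bits: int
    kind: str
    bits: frozenset[int] | None = None
    counts: dict[int, int] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.bits if self.bits is not None else self.counts.keys()
        if any(i < 0 or i >= self.n_bits for i in idx):
            raise ValueError("fingerprint index outside [0, n_bits)")


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def _fp_generator(kind: str, params: dict):
    if kind in ("morgan_bits", "morgan_counts"):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=params.get("radius", MORGAN_RADIUS),
            fpSize=params.get("n_bits", MORGAN_NBITS),
        )
    if kind == "path_fp":
        return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=params.get("n_bits", MORGAN_NBITS))
    if kind == "torsion_fp":
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            fpSize=params.get("n_bits", MORGAN_NBITS)
        )
    if kind == "atompair_fp":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=params.get("n_bits", MORGAN_NBITS))
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def descriptors(smiles_list: Sequence[str]) -> FeatureMatrix:
    """Full built-in RDKit descriptor set for each molecule.

    Non-finite policy: columns that are non-finite for every row are dropped;
    remaining non-finite holes are median-imputed. The policy and backend
    version are recorded in ``encoder_params``.
    """
    names = [n for n, _ in Descriptors.descList]
    rows, keys, errors = [], [], {}
    for smi in smiles_list:
        mol = _mol(smi)
        if mol is None:
            errors[smi] = "unparseable SMILES"
            continue
        vals = []
        for _, fn in Descriptors.descList:
            try:
                vals.append(float(fn(mol)))
            except Exception:  # individual descriptor failure -> hole
                vals.append(np.nan)
        rows.append(vals)
        keys.append(smi)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    values[~np.isfinite(values)] = np.nan
    keep = ~np.all(np.isnan(values), axis=0) if len(rows) else np.ones(len(names), bool)
    values = values[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    if len(rows):
        med = np.nanmedian(values, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        holes = np.isnan(values)
        values[holes] = np.broadcast_to(med, values.shape)[holes]
    return FeatureMatrix(
        values=values,
        feature_names=kept_names,
        encoder_id="descriptors",
        encoder_params={
            "backend": "rdkit",
            "backend_version": rdkit.__version__,
            "nan_policy": "drop-all-nan-columns-then-median-impute",
        },
        row_keys=keys,
        errors=errors,
    )


def _single_fingerprint(mol, kind: str, params: dict) -> Fingerprint:
    p = dict(params)
    if kind == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
        return Fingerprint(n_bits=MACCS_NBITS, kind=kind, bits=frozenset(fp.GetOnBits()), params=p)
    gen = _fp_generator(kind, p)
    n_bits = p.get("n_bits", MORGAN_NBITS)
    if kind == "morgan_counts":
        sv = gen.GetCountFingerprint(mol)
        return Fingerprint(
            n_bits=n_bits, kind=kind, counts={int(k): int(v) for k, v in sv.GetNonzeroElements().items()}, params=p
        )
    fp = gen.GetFingerprint(mol)
    return Fingerprint(n_bits=n_bits, kind=kind, bits=frozenset(fp.GetOnBits()), params=p)


def fingerprints(smiles_list: Sequence[str], kind: str = "morgan_bits", **params) -> list[Fingerprint]:
    """Per-molecule sparse fingerprints; raises on unparseable SMILES."""
    if kind not in ENCODERS or kind == "descriptors":
        raise ValueError(f"kind must be one of {ENCODERS[1:]}, got {kind!r}")
    out = []
    for smi in smiles_list:
        mol = _mol(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        out.append(_single_fingerprint(mol, kind, params))
    return out


def fingerprint(smiles_list: Sequence[str], kind: str = "morgan_bits", **params) -> FeatureMatrix:
    """Dense fingerprint feature matrix (bit or count form)."""
    if kind not in ENCODERS or kind == "descriptors":
        raise ValueError(f"kind must be one of {ENCODERS[1:]}, got {kind!r}")
    rows, keys, errors = [], [], {}
    n_bits = MACCS_NBITS if kind == "maccs" else params.get("n_bits", MORGAN_NBITS)
    for smi in smiles_list:
        mol = _mol(smi)
        if mol is None:
            errors[smi] = "unparseable SMILES"
            continue
        fp = _single_fingerprint(mol, kind, params)
        row = np.zeros(n_bits)
        if fp.bits is not None:
            row[list(fp.bits)] = 1.0
        else:
            for i, c in fp.counts.items():
                row[i] = float(c)
        rows.append(row)
        keys.append(smi)
    eff = {"radius": MORGAN_RADIUS, "n_bits": n_bits, **params} if kind.startswith("morgan") else {"n_bits": n_bits, **params}
    return FeatureMatrix(
        values=np.asarray(rows) if rows else np.empty((0, n_bits)),
        feature_names=[f"{kind}_{i}" for i in range(n_bits)],
        encoder_id=kind,
        encoder_params={"backend_version": rdkit.__version__, **eff},
        row_keys=keys,
        errors=errors,
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity |a∩b| / |a∪b| of two same-kind fingerprints.

    Two empty fingerprints are defined as dissimilar (0.0) so that downstream
    similarity grouping never merges featureless molecules.
    """
    if a.n_bits != b.n_bits or a.kind != b.kind:
        raise ValueError("fingerprints have mismatched kind or length")
    if a.counts is not None:
        keys = set(a.counts) | set(b.counts or {})
        inter = sum(min(a.counts.get(k, 0), (b.counts or {}).get(k, 0)) for k in keys)
        union = sum(max(a.counts.get(k, 0), (b.counts or {}).get(k, 0)) for k in keys)
    else:
        inter = len(a.bits & b.bits)
        union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return inter / union


class DescriptorFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer over SMILES lists producing RDKit descriptor vectors."""

    def fit(self, X, y=None):
        self.feature_names_ = descriptors(list(X)[:1]).feature_names
        return self

    def transform(self, X) -> np.ndarray:
        fm = descriptors(list(X))
        if fm.errors:
            raise ValueError(f"unparseable SMILES in transform: {sorted(fm.errors)}")
        return fm.values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_)


class FingerprintFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer over SMILES lists producing dense fingerprints."""

    def __init__(self, kind: str = "morgan_bits", radius: int = MORGAN_RADIUS, n_bits: int = MORGAN_NBITS):
        self.kind = kind
        self.radius = radius
        self.n_bits = n_bits

    def _params(self) -> dict:
        if self.kind.startswith("morgan"):
            return {"radius": self.radius, "n_bits": self.n_bits}
        if self.kind == "maccs":
            return {}
        return {"n_bits": self.n_bits}

    def fit(self, X, y=None):
        self.n_features_out_ = MACCS_NBITS if self.kind == "maccs" else self.n_bits
        return self

    def transform(self, X) -> np.ndarray:
        fm = fingerprint(list(X), kind=self.kind, **self._params())
        if fm.errors:
            raise ValueError(f"unparseable SMILES in transform: {sorted(fm.errors)}")
        return fm.values
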