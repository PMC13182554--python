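"""Two-source label curation for the ordinal odor-strength dataset.

Raw records carry either a categorical strength label (source A, a
Good-Scents-like vendor list) or a free-text odor description (source B, a
PubChem-like description corpus). Curation canonicalizes SMILES, maps
descriptions to the four-level ordinal scale with an ordered keyword table,
filters invalid / multi-fragment / duplicate entries, merges the sources, and
quantifies inter-source agreement with quadratic-weighted Cohen's kappa (on
the overlap) and ordinal Krippendorff's alpha (on the full two-source table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: ordinal scale: odorless(0) < low(1) < medium(2) < high(3)
CATEGORIES = ("odorless", "low", "medium", "high")
N_CATEGORIES = 4


@dataclass(frozen=True)
class OrdinalScale:
    categories: tuple[str, ...] = CATEGORIES

    def code(self, name: str) -> int:
        return self.categories.index(name)

    def name(self, code: int) -> str:
        return self.categories[code]


#: Ordered keyword table: first substring match wins. Keywords are
#: illustrative defaults for description-to-category mapping; shipped as
#: data so deployments can swap their own table in.
DEFAULT_KEYWORDS: tuple[tuple[str, int], ...] = (
    ("odorless", 0),
    ("odourless", 0),
    ("no odor", 0),
    ("no smell", 0),
    ("very strong", 3),
    ("strong", 3),
    ("powerful", 3),
    ("intense", 3),
    ("pungent", 3),
    ("penetrating", 3),
    ("faint", 1),
    ("weak", 1),
    ("slight", 1),
    ("mild", 1),
    ("delicate", 1),
    ("moderate", 2),
    ("distinct", 2),
    ("noticeable", 2),
    ("characteristic odor", 2),
)

#: textual labels accepted on categorical-label records
TEXT_LABELS = {"odorless": 0, "low": 1, "medium": 2, "high": 3, "very high": 3}

AUDIT_FLAGS = (
    "invalid_smiles",
    "dot_smiles",
    "duplicate",
    "reclassified_very_high",
    "unmapped_description",
)


@dataclass
class MoleculeRecord:
    """One molecule annotation from one source."""

    smiles_raw: str
    source: str  # "A" or "B"
    description: str | None = None
    strength: int | None = None
    smiles_canonical: str | None = None
    audit_flags: set[str] = field(default_factory=set)

    def copy(self) -> "MoleculeRecord":
        return replace(self, audit_flags=set(self.audit_flags))


@dataclass
class KeywordTable:
    """Ordered (keyword, category-code) pairs; case-insensitive substring match."""

    entries: tuple[tuple[str, int], ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        kws = [k for k, _ in self.entries]
        if len(set(kws)) != len(kws):
            raise ValueError("duplicate keywords in table")
        if any(not k for k in kws):
            raise ValueError("empty keyword in table")
        if any(c not in range(N_CATEGORIES) for _, c in self.entries):
            raise ValueError("category code outside 0..3")


@dataclass
class AgreementReport:
    kappa_quadratic: float
    krippendorff_alpha: float
    n_overlap: int
    contingency: np.ndarray
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kappa_quadratic": self.kappa_quadratic,
            "krippendorff_alpha": self.krippendorff_alpha,
            "n_overlap": self.n_overlap,
            "contingency": self.contingency.tolist(),
            "degenerate": self.degenerate,
        }


CANONICALIZATION_FAILED = "__canonicalization_failed__"


def canonicalize(smiles: str) -> str:
    """RDKit canonical SMILES, or the failure marker for unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return CANONICALIZATION_FAILED
    return Chem.MolToSmiles(mol)


def map_description(text: str, table: KeywordTable | None = None) -> int | None:
    """First keyword (in table order) found as a case-insensitive substring."""
    table = table or KeywordTable()
    low = text.lower()
    for kw, code in table.entries:
        if kw in low:
            return code
    return None


def annotate(records: Iterable[MoleculeRecord], table: KeywordTable | None = None) -> list[MoleculeRecord]:
    """Canonicalize SMILES and resolve strengths from text labels/descriptions."""
    out = []
    for rec in records:
        rec = rec.copy()
        rec.smiles_canonical = None
        canon = canonicalize(rec.smiles_raw)
        if canon != CANONICALIZATION_FAILED:
            rec.smiles_canonical = canon
        if rec.strength is None and rec.description is not None:
            if rec.description.strip().lower() in TEXT_LABELS:
                label = rec.description.strip().lower()
                rec.strength = TEXT_LABELS[label]
                if label == "very high":
                    rec.audit_flags.add("reclassified_very_high")
            else:
                code = map_description(rec.description, table)
                if code is None:
                    rec.audit_flags.add("unmapped_description")
                else:
                    rec.strength = code
        out.append(rec)
    return out


def apply_filters(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Drop invalid / dotted / unlabeled records; dedupe within source B.

    Returns retained records and an audit log counting every removal or
    relabel by reason (conservation: input = retained + removals).
    """
    audit = {
        "input": len(records),
        "invalid_smiles": 0,
        "dot_smiles": 0,
        "duplicate": 0,
        "unmapped_description": 0,
        "reclassified_very_high": 0,
        "retained": 0,
    }
    retained: list[MoleculeRecord] = []
    seen_b: set[str] = set()
    for rec in records:
        rec = rec.copy()
        if "." in rec.smiles_raw:
            rec.audit_flags.add("dot_smiles")
            audit["dot_smiles"] += 1
            continue
        if rec.smiles_canonical is None:
            rec.audit_flags.add("invalid_smiles")
            audit["invalid_smiles"] += 1
            continue
        if rec.strength is None:
            rec.audit_flags.add("unmapped_description")
            audit["unmapped_description"] += 1
            continue
        if rec.source == "B":
            if rec.smiles_canonical in seen_b:
                rec.audit_flags.add("duplicate")
                audit["duplicate"] += 1
                continue
            seen_b.add(rec.smiles_canonical)
        if "reclassified_very_high" in rec.audit_flags:
            audit["reclassified_very_high"] += 1
        retained.append(rec)
    audit["retained"] = len(retained)
    return retained, audit


def merge_sources(
    records_a: Sequence[MoleculeRecord],
    records_b: Sequence[MoleculeRecord],
    precedence: str = "A",
) -> tuple[list[MoleculeRecord], list[tuple[int, int]]]:
    """Union on canonical SMILES.

    On conflict the configured precedence source's label is kept; both
    originals go to the overlap table (label_A, label_B) for agreement
    analysis. Within-list duplicates keep the first occurrence.
    """
    if precedence not in ("A", "B"):
        raise ValueError("precedence must be 'A' or 'B'")
    by_a = {}
    for r in records_a:
        by_a.setdefault(r.smiles_canonical, r)
    by_b = {}
    for r in records_b:
        by_b.setdefault(r.smiles_canonical, r)
    merged, overlap = [], []
    for smi, ra in by_a.items():
        if smi in by_b:
            rb = by_b[smi]
            overlap.append((ra.strength, rb.strength))
            merged.append(ra.copy() if precedence == "A" else rb.copy())
        else:
            merged.append(ra.copy())
    for smi, rb in by_b.items():
        if smi not in by_a:
            merged.append(rb.copy())
    return merged, overlap


def quadratic_weighted_kappa(pairs: Sequence[tuple[int, int]], n_categories: int = N_CATEGORIES) -> float:
    """Cohen's kappa with quadratic disagreement weights w_ij = (i-j)^2/(K-1)^2.

    kappa = 1 - sum(w * O) / sum(w * E), with E the outer product of the
    marginals. Returns NaN when the expected weighted disagreement is zero
    (all annotations in one category).
    """
    if len(pairs) == 0:
        raise ValueError("kappa requires at least one pair")
    obs = np.zeros((n_categories, n_categories))
    for a, b in pairs:
        obs[a, b] += 1
    obs /= obs.sum()
    i = np.arange(n_categories)
    w = (i[:, None] - i[None, :]) ** 2 / (n_categories - 1) ** 2
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    denom = float((w * exp).sum())
    if denom == 0.0:
        return float("nan")
    return 1.0 - float((w * obs).sum()) / denom


def krippendorff_alpha_ordinal(table: np.ndarray) -> float:
    """Ordinal-level Krippendorff's alpha from a units x coders value table.

    ``table`` holds ordinal codes with NaN for missing annotations. Uses the
    coincidence-matrix formulation with the ordinal difference
    delta(c,k)^2 = (sum_{g=c}^{k} n_g - (n_c + n_k)/2)^2 where n_g are
    coincidence marginals. Units with fewer than two annotations are
    unpairable and drop out. Returns NaN when expected disagreement is zero.
    """
    table = np.asarray(table, dtype=float)
    values = np.unique(table[np.isfinite(table)])
    if values.size == 0:
        return float("nan")
    vidx = {v: i for i, v in enumerate(values)}
    k = values.size
    coincidence = np.zeros((k, k))
    for unit in table:
        vals = unit[np.isfinite(unit)]
        m = len(vals)
        if m < 2:
            continue
        for ia, a in enumerate(vals):
            for ib, b in enumerate(vals):
                if ia != ib:
                    coincidence[vidx[a], vidx[b]] += 1.0 / (m - 1)
    n = coincidence.sum()
    if n == 0:
        return float("nan")
    marg = coincidence.sum(axis=1)
    # ordinal metric on the *values'* coincidence marginals
    delta2 = np.zeros((k, k))
    for c in range(k):
        for d in range(c + 1, k):
            span = marg[c : d + 1].sum() - (marg[c] + marg[d]) / 2.0
            delta2[c, d] = delta2[d, c] = span**2
    d_obs = (coincidence * delta2).sum() / n
    d_exp = (np.outer(marg, marg) * delta2).sum() / (n * (n - 1))
    if d_exp == 0:
        return float("nan")
    return float(1.0 - d_obs / d_exp)


def agreement(
    overlap_pairs: Sequence[tuple[int, int]],
    full_a: dict[str, int] | None = None,
    full_b: dict[str, int] | None = None,
) -> AgreementReport:
    """Inter-source agreement: kappa on the overlap, alpha on the full table.

    ``full_a``/``full_b`` map canonical SMILES to labels for each complete
    source; when omitted, alpha is computed on the overlap pairs alone.
    """
    if len(overlap_pairs) == 0:
        raise ValueError("agreement requires a nonempty overlap")
    contingency = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    for a, b in overlap_pairs:
        contingency[a, b] += 1
    kappa = quadratic_weighted_kappa(overlap_pairs)
    if full_a is not None and full_b is not None:
        keys = sorted(set(full_a) | set(full_b))
        tab = np.full((len(keys), 2), np.nan)
        for i, key in enumerate(keys):
            if key in full_a:
                tab[i, 0] = full_a[key]
            if key in full_b:
                tab[i, 1] = full_b[key]
    else:
        tab = np.asarray(overlap_pairs, dtype=float)
    alpha = krippendorff_alpha_ordinal(tab)
    return AgreementReport(
        kappa_quadratic=kappa,
        krippendorff_alpha=alpha,
        n_overlap=len(overlap_pairs),
        contingency=contingency,
        degenerate=bool(np.isnan(kappa) or np.isnan(alpha)),
    )


def curate(
    records: Sequence[MoleculeRecord],
    table: KeywordTable | None = None,
    precedence: str = "A",
) -> tuple[list[MoleculeRecord], dict, AgreementReport | None]:
    """Full curation pass: annotate -> filter per source -> merge -> agreement."""
    annotated = annotate(records, table)
    rec_a, audit_a = apply_filters([r for r in annotated if r.source == "A"])
    rec_b, audit_b = apply_filters([r for r in annotated if r.source == "B"])
    merged, overlap = merge_sources(rec_a, rec_b, precedence=precedence)
    report = None
    if overlap:
        full_a = {r.smiles_canonical: r.strength for r in rec_a}
        full_b = {r.smiles_canonical: r.strength for r in rec_b}
        report = agreement(overlap, full_a, full_b)
    audit = {"source_A": audit_a, "source_B": audit_b, "n_merged": len(merged), "n_overlap": len(overlap)}
    return merged, audit, report


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smiles": [r.smiles_raw for r in records],
            "smiles_canonical": [r.smiles_canonical for r in records],
            "source": [r.source for r in records],
            "description": [r.description for r in records],
            "strength": [r.strength for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[MoleculeRecord]:
    """Read records from the standard CSV layout (smiles, source, description, strength)."""
    records = []
    for _, row in frame.iterrows():
        strength = row.get("strength")
        if pd.isna(strength):
            strength = None
        elif isinstance(strength, str):
            strength = TEXT_LABELS.get(strength.strip().lower())
        else:
            strength = int(strength)
        desc = row.get("description")
        records.append(
            MoleculeRecord(
                smiles_raw=str(row["smiles"]),
                source=str(row["source"]),
                description=None if pd.isna(desc) else str(desc),
                strength=strength,
            )
        )
    return records


def write_outputs(path_prefix: str, records: Sequence[MoleculeRecord], audit: dict, report: AgreementReport | None) -> None:
    records_to_frame(records).to_csv(f"{path_prefix}_curated.csv", index=False)
    with open(f"{path_prefix}_audit.json", "w") as fh:
        json.dump(audit, fh, indent=2)
    if report is not None:
        with open(f"{path_prefix}_agreement.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
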