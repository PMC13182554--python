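"""Synthetic two-source odor-strength dataset generator.

Real odor-strength labels come from copyrighted vendor catalogues, so testable
development needs a generator that reproduces the *statistical shape* of that
data: chemically valid and diverse molecules, a four-level ordinal label driven
by mass-transport-related properties (molecular weight, lipophilicity,
hydrogen-bonding polarity), two annotation sources with different class skews,
a molecule overlap between sources, and adjacent-category label noise.

Molecules come from a documented fragment grammar: an alkyl or alkenyl
backbone of 2-14 carbons decorated with 0-3 terminal functional groups drawn
from {alcohol, aldehyde, ketone, ester, ether, carboxylic acid, amine,
nitrile, thiol, aromatic ring}. Every emitted SMILES is RDKit-canonical and
unique within a dataset; molecular weights span roughly 30-400 Da so the
latent strength function has signal.

The latent model is a tent function of volatility/polarity:

    s = beta0 - beta_mw*|MW - mu_mw| - beta_logp*|logP - mu_logp|
        + beta_polarity*(HBD + HBA) + Normal(0, noise_sd)

thresholded at tau1 < tau2 < tau3 into odorless(0) < low(1) < medium(2) <
high(3). Default coefficients and thresholds were set once by Monte-Carlo
quantiles of s over the grammar population so that, before per-source
steering, medium is the majority class and low is a ~12% minority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import featurize
from .curation import CATEGORIES, MoleculeRecord

#: grammar pieces: (name, SMILES fragment appended to the backbone)
FUNCTIONAL_GROUPS: tuple[tuple[str, str], ...] = (
    ("alcohol", "O"),
    ("aldehyde", "C=O"),
    ("ketone", "C(C)=O"),
    ("ester", "C(=O)OC"),
    ("ether", "OC"),
    ("carboxylic_acid", "C(=O)O"),
    ("amine", "N"),
    ("nitrile", "C#N"),
    ("thiol", "S"),
    ("aromatic", "c1ccccc1"),
)

MIN_CHAIN, MAX_CHAIN = 2, 14
#: conservative unique-structure capacity of the grammar
GRAMMAR_CAPACITY = 4000

#: phrase bank for free-text descriptions emitted by the PubChem-like source
DESCRIPTION_PHRASES: dict[int, tuple[str, ...]] = {
    0: ("Colorless, odorless liquid.", "An odorless compound.", "No odor detectable."),
    1: ("Faint fruity odor.", "Weak sweet smell.", "Slight ethereal odor."),
    2: ("Distinct fruity odor.", "Moderate floral smell.", "Noticeable green odor."),
    3: ("Strong pungent odor.", "Powerful penetrating smell.", "Intense fruity odor."),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the curated two-source data: source A (vendor-like)
    skewed to medium/high, source B (description-like) skewed to
    odorless/low, combined majority medium with low around 12%, and
    adjacent-flip label noise placing the overlap quadratic-weighted kappa
    near the ~0.8 agreement regime.
    """

    n_molecules: int = 1000
    seed: int = 0
    source_mix: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.08, 0.06, 0.50, 0.36),  # source A targets over (odorless, low, medium, high)
        (0.35, 0.26, 0.25, 0.14),  # source B targets
    )
    source_weight_a: float = 0.7  # share of single-source molecules going to A
    overlap_fraction: float = 0.3
    label_noise: float = 0.18
    steer_sources: bool = True  # rejection-resample toward source_mix targets
    # latent tent-function coefficients
    beta0: float = 1.0
    beta_mw: float = 0.012
    beta_logp: float = 0.35
    beta_polarity: float = 0.25
    mu_mw: float = 140.0
    mu_logp: float = 2.0
    noise_sd: float = 0.3
    # thresholds: calibrated from Monte-Carlo quantiles of the latent score
    tau1: float = -0.84
    tau2: float = -0.26
    tau3: float = 1.05

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        for mix in self.source_mix:
            if len(mix) != 4 or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("each source mix needs 4 probabilities summing to 1")
        if not (self.tau1 < self.tau2 < self.tau3):
            raise ValueError("thresholds must satisfy tau1 < tau2 < tau3")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (self.tau1, self.tau2, self.tau3)


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]
    smiles: list[str]
    latent_scores: np.ndarray
    true_labels: np.ndarray
    descriptors: featurize.FeatureMatrix | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"smiles": self.smiles, "latent_score": self.latent_scores, "true_label": self.true_labels}
        )


def _rngs(seed: int, n_streams: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n_streams)]


def _sample_smiles(rng: np.random.Generator) -> str:
    chain = int(rng.integers(MIN_CHAIN, MAX_CHAIN + 1))
    backbone = "C" * chain
    if chain >= 3 and rng.random() < 0.3:  # one alkenyl bond
        backbone = "C=C" + "C" * (chain - 2)
    n_groups = int(rng.choice([0, 1, 2, 3], p=[0.15, 0.45, 0.30, 0.10]))
    picks = rng.choice(len(FUNCTIONAL_GROUPS), size=n_groups, replace=True)
    return backbone + "".join(FUNCTIONAL_GROUPS[i][1] for i in picks)


def generate_molecules(config: GeneratorConfig) -> list[str]:
    """Unique canonical SMILES from the fragment grammar, seeded."""
    if config.n_molecules > GRAMMAR_CAPACITY:
        raise ValueError(
            f"n_molecules={config.n_molecules} exceeds the fragment grammar's "
            f"unique-structure capacity (~{GRAMMAR_CAPACITY}); lower n_molecules"
        )
    rng = _rngs(config.seed, 3)[0]
    seen: set[str] = set()
    out: list[str] = []
    attempts, max_attempts = 0, 200 * config.n_molecules
    from .curation import canonicalize, CANONICALIZATION_FAILED

    while len(out) < config.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("grammar failed to produce enough unique structures")
        canon = canonicalize(_sample_smiles(rng))
        if canon == CANONICALIZATION_FAILED or canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def latent_score_noiseless(config: GeneratorConfig, mw: np.ndarray, logp: np.ndarray, polarity: np.ndarray) -> np.ndarray:
    return (
        config.beta0
        - config.beta_mw * np.abs(mw - config.mu_mw)
        - config.beta_logp * np.abs(logp - config.mu_logp)
        + config.beta_polarity * polarity
    )


def threshold_labels(scores: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    t1, t2, t3 = thresholds
    return (scores >= t1).astype(int) + (scores >= t2) + (scores >= t3)


def assign_labels(smiles: Sequence[str], config: GeneratorConfig) -> SyntheticDataset:
    """Attach latent scores and noise-free true labels to generated molecules."""
    desc = featurize.descriptors(smiles)
    if desc.errors:
        raise ValueError(f"featurization failed for {sorted(desc.errors)}")
    mw = desc.column("MolWt")
    logp = desc.column("MolLogP")
    polarity = desc.column("NumHDonors") + desc.column("NumHAcceptors")
    rng = _rngs(config.seed, 3)[1]
    scores = latent_score_noiseless(config, mw, logp, polarity)
    if config.noise_sd > 0:
        scores = scores + rng.normal(0.0, config.noise_sd, size=len(scores))
    labels = threshold_labels(scores, config.thresholds)
    return SyntheticDataset(
        records=[], smiles=list(smiles), latent_scores=scores, true_labels=labels, descriptors=desc
    )


def flip_adjacent(labels: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Adjacent-category flips with probability p; boundaries flip inward."""
    out = labels.copy()
    flip = rng.random(len(labels)) < p
    direction = np.where(rng.random(len(labels)) < 0.5, -1, 1)
    direction[out == 0] = 1
    direction[out == 3] = -1
    out[flip] += direction[flip]
    return out


def _steer_to_mix(
    idx: np.ndarray, labels: np.ndarray, mix: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Rejection-resample member indices toward a target class mix.

    Keep probability per class c is proportional to target_c / observed_c,
    scaled so the best-represented class is kept with probability 1; ground
    truth is untouched.
    """
    if len(idx) == 0:
        return idx
    obs = np.bincount(labels, minlength=4) / len(labels)
    with np.errstate(divide="ignore"):
        ratio = np.where(obs > 0, np.asarray(mix) / obs, 0.0)
    if ratio.max() == 0:
        return idx
    keep_p = ratio / ratio.max()
    keep = rng.random(len(idx)) < keep_p[labels]
    return idx[keep]


def emit_two_source_dataset(dataset: SyntheticDataset, config: GeneratorConfig) -> list[MoleculeRecord]:
    """Materialize per-source annotation records with noise and class steering.

    Each molecule is annotated by both sources (probability overlap_fraction)
    or by a single source (A with probability source_weight_a). Each
    annotation independently applies adjacent-category label noise; each
    source is then rejection-resampled toward its class-mix target. Source A
    emits categorical strength labels, source B emits free-text descriptions
    containing mappable keywords.
    """
    rng = _rngs(config.seed, 3)[2]
    n = len(dataset.smiles)
    u = rng.random(n)
    in_both = u < config.overlap_fraction
    in_a_only = (~in_both) & (rng.random(n) < config.source_weight_a)
    in_b_only = ~(in_both | in_a_only)

    members = {"A": np.where(in_both | in_a_only)[0], "B": np.where(in_both | in_b_only)[0]}
    records: list[MoleculeRecord] = []
    for s_i, source in enumerate(("A", "B")):
        idx = members[source]
        noisy = flip_adjacent(dataset.true_labels[idx], config.label_noise, rng)
        if config.steer_sources:
            kept_mask = np.isin(idx, _steer_to_mix(idx, noisy, config.source_mix[s_i], rng))
        else:
            kept_mask = np.ones(len(idx), dtype=bool)
        for j, keep in zip(range(len(idx)), kept_mask):
            if not keep:
                continue
            i, lab = idx[j], int(noisy[j])
            smi = dataset.smiles[i]
            if source == "A":
                records.append(
                    MoleculeRecord(smiles_raw=smi, source="A", description=CATEGORIES[lab], strength=None)
                )
            else:
                phrases = DESCRIPTION_PHRASES[lab]
                text = phrases[int(rng.integers(len(phrases)))]
                records.append(MoleculeRecord(smiles_raw=smi, source="B", description=text, strength=None))
    return records


def generate_dataset(config: GeneratorConfig) -> tuple[list[MoleculeRecord], SyntheticDataset]:
    """Full generation pass: grammar -> latent labels -> two-source records."""
    smiles = generate_molecules(config)
    dataset = assign_labels(smiles, config)
    records = emit_two_source_dataset(dataset, config)
    dataset.records = records
    return records, dataset


def monte_carlo_category_probabilities(
    config: GeneratorConfig, smiles: Sequence[str], n_draws: int = 100_000, seed: int = 123
) -> np.ndarray:
    """Monte-Carlo integration of the latent model's category probabilities.

    Draws molecules uniformly from ``smiles`` and latent noise from
    Normal(0, noise_sd); returns the 4-vector of category probabilities.
    Serves as the independent oracle for the label-frequency checks.
    """
    desc = featurize.descriptors(smiles)
    mw = desc.column("MolWt")
    logp = desc.column("MolLogP")
    polarity = desc.column("NumHDonors") + desc.column("NumHAcceptors")
    base = latent_score_noiseless(config, mw, logp, polarity)
    rng = np.random.Generator(np.random.PCG64(seed))
    picks = rng.integers(len(base), size=n_draws)
    scores = base[picks] + rng.normal(0.0, config.noise_sd, size=n_draws)
    labels = threshold_labels(scores, config.thresholds)
    return np.bincount(labels, minlength=4) / n_draws


def write_dataset(path_prefix: str, records: Sequence[MoleculeRecord], dataset: SyntheticDataset) -> None:
    """Standard record CSV plus hidden-truth sidecar for tests."""
    pd.DataFrame(
        {
            "smiles": [r.smiles_raw for r in records],
            "source": [r.source for r in records],
            "description": [r.description for r in records],
            "strength": [r.strength for r in records],
        }
    ).to_csv(f"{path_prefix}_records.csv", index=False)
    dataset.truth_frame().to_csv(f"{path_prefix}_truth.csv", index=False)
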