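"""Synthetic neonatal-airway cohort generator.

Emulates the structure the downstream analysis assumes without any real
sequencing data: a samples x ASV count table whose counts arise from a
log-normal *basis* abundance model closed to multinomial read counts, with
group-specific planted correlation blocks (the ground-truth co-occurrence
structure), organelle-contaminant lineages, exact-singleton ASVs, and clinical
metadata whose means shift with disease grade (gestational age and birth
weight decrease as severity increases).

The generative model is the one compositionally robust correlation methods
assume: latent absolute abundances ``a_ij = exp(x_ij)`` with ``x`` multivariate
normal (correlation blocks planted per group), observed fractions
``f_ij = a_ij / sum_j a_ij`` and counts ``c_i ~ Multinomial(depth_i, f_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUP_LEVELS, CountTable, SampleMetadata, TaxonomyTable

# Genera commonly reported in neonatal lower-airway 16S surveys; the first few
# dominate the community.  Lineages are (domain..genus).
_GENUS_POOL = [
    ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    ("Bacteria", "Pseudomonadota", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Pelomonas"),
    ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Xanthomonadales", "Xanthomonadaceae", "Stenotrophomonas"),
    ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella"),
    ("Bacteria", "Bacillota", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Bacteria", "Bacteroidota", "Flavobacteriia", "Flavobacteriales", "Weeksellaceae", "Chryseobacterium"),
    ("Bacteria", "Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Caulobacterales", "Caulobacteraceae", "Brevundimonas"),
    ("Bacteria", "Bacillota", "Bacilli", "Staphylococcales", "Staphylococcaceae", "Staphylococcus"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
]

_CHLOROPLAST_LINEAGE = ("Bacteria", "Cyanobacteriota", "Cyanophyceae", "Chloroplast", "", "")
_MITOCHONDRIA_LINEAGE = ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Rickettsiales", "Mitochondria", "")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Study-scale defaults for the synthetic cohort.

    ``planted_modules`` maps each group to a list of ``(block_size, rho)``
    pairs: within each block the latent log-abundances share pairwise basis
    correlation ``rho`` in that group only.  Blocks are allocated disjoint
    taxon index ranges across all groups so each group has its own signature
    structure; the defaults give the severest grade a collapsed (tiny, weak)
    network relative to the others.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"non": 31, "I": 31, "II": 20, "III": 16}
    )
    n_taxa: int = 300
    depth_range: tuple = (22_026, 72_630)
    planted_modules: dict = field(
        default_factory=lambda: {
            "non": [(20, 0.7)],
            "I": [(25, 0.7)],
            "II": [(30, 0.75)],
            "III": [(5, 0.6)],
        }
    )
    basis_log_mean_sd: float = 2.0  # spread of per-taxon log means -> genus dominance
    basis_log_sd: float = 1.0      # per-taxon log-abundance s.d.
    n_contaminant_taxa: int = 10
    n_singleton_taxa: int = 20
    gestational_age_slope: float = -0.9   # weeks per grade
    birth_weight_slope: float = -130.0    # grams per grade
    dm_overdispersion: float = 0.0        # Dirichlet-multinomial theta; 0 = plain multinomial
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUP_LEVELS:
                raise ConfigError(f"unknown group {g!r}")
            if n < 2:
                raise ConfigError(f"group {g!r} must have >= 2 samples")
        total_block = sum(s for mods in self.planted_modules.values() for s, _ in mods)
        if total_block > self.n_taxa:
            raise ConfigError(
                f"planted blocks cover {total_block} taxa, exceeding n_taxa={self.n_taxa}"
            )
        for mods in self.planted_modules.values():
            for size, rho in mods:
                if not -1.0 < rho < 1.0:
                    raise ConfigError(f"planted rho {rho} outside (-1, 1)")
                if size < 2:
                    raise ConfigError("planted blocks need >= 2 taxa")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ConfigError(f"invalid depth range {self.depth_range}")


def planted_block_indices(config: CohortConfig) -> dict:
    """Disjoint taxon index ranges per group, allocated in group order."""
    out: dict = {}
    start = 0
    for g in GROUP_LEVELS:
        blocks = []
        for size, rho in config.planted_modules.get(g, []):
            blocks.append((list(range(start, start + size)), rho))
            start += size
        out[g] = blocks
    return out


def _block_cholesky(n: int, blocks) -> np.ndarray:
    corr = np.eye(n)
    for idx, rho in blocks:
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = rho
    return np.linalg.cholesky(corr)


def _draw_counts(rng: np.random.Generator, depth: int, fractions: np.ndarray,
                 theta: float) -> np.ndarray:
    if theta > 0:
        fractions = rng.dirichlet(fractions / theta)
    return rng.multinomial(depth, fractions)


def generate_cohort(config: CohortConfig):
    """Generate ``(CountTable, TaxonomyTable, SampleMetadata)`` for one cohort.

    Deterministic under ``config.seed``.  Row sums equal the drawn depths
    exactly; designated singleton taxa have grand total exactly 1 (and no
    other taxon does); contaminant taxa carry Chloroplast / Mitochondria
    lineages.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_core = config.n_taxa
    n_cont = config.n_contaminant_taxa
    n_single = config.n_singleton_taxa
    n_basis = n_core + n_cont
    blocks = planted_block_indices(config)

    # per-taxon log-mean: heavy tail -> a handful of dominant taxa/genera
    mu = rng.normal(0.0, config.basis_log_mean_sd, size=n_basis)
    mu[n_core:] -= 1.0  # contaminants moderately rare on average

    chol = {g: _block_cholesky(n_basis, blocks[g]) for g in GROUP_LEVELS}

    sample_ids, group_of = [], []
    for g in GROUP_LEVELS:
        for k in range(config.group_sizes.get(g, 0)):
            sample_ids.append(f"S_{g}_{k + 1:02d}")
            group_of.append(g)

    n_samples = len(sample_ids)
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n_samples)

    # host sample for each singleton taxon
    singleton_host = rng.integers(0, n_samples, size=n_single)
    hosted = np.bincount(singleton_host, minlength=n_samples)

    counts = np.zeros((n_samples, n_basis), dtype=np.int64)
    for i, g in enumerate(group_of):
        z = rng.standard_normal(n_basis)
        x = mu + config.basis_log_sd * (chol[g] @ z)
        basis = np.exp(x - x.max())  # stable normalisation
        fractions = basis / basis.sum()
        budget = int(depths[i]) - int(hosted[i])
        counts[i] = _draw_counts(rng, budget, fractions, config.dm_overdispersion)

    # accidental basis-taxon singletons would blur the designed count; fold the
    # stray read into the sample's most abundant taxon (depth preserved)
    totals = counts.sum(axis=0)
    for j in np.flatnonzero(totals == 1):
        i = int(np.flatnonzero(counts[:, j] == 1)[0])
        counts[i, j] = 0
        counts[i, int(np.argmax(counts[i]))] += 1

    singleton_counts = np.zeros((n_samples, n_single), dtype=np.int64)
    for s, host in enumerate(singleton_host):
        singleton_counts[host, s] = 1

    all_counts = np.hstack([counts, singleton_counts])
    taxon_ids = (
        [f"ASV_{j + 1}" for j in range(n_core)]
        + [f"ASV_org_{j + 1}" for j in range(n_cont)]
        + [f"ASV_sing_{j + 1}" for j in range(n_single)]
    )
    table = CountTable(sample_ids, taxon_ids, all_counts)

    # taxonomy: dominant taxa concentrated in a few genera (Zipf-ish weights)
    weights = 1.0 / np.arange(1, len(_GENUS_POOL) + 1) ** 1.3
    weights /= weights.sum()
    lineages = {}
    for j in range(n_core):
        lineages[taxon_ids[j]] = _GENUS_POOL[rng.choice(len(_GENUS_POOL), p=weights)]
    for j in range(n_cont):
        lin = _CHLOROPLAST_LINEAGE if j % 2 == 0 else _MITOCHONDRIA_LINEAGE
        lineages[taxon_ids[n_core + j]] = lin
    for j in range(n_single):
        lineages[taxon_ids[n_core + n_cont + j]] = _GENUS_POOL[
            rng.choice(len(_GENUS_POOL), p=weights)
        ]
    taxonomy = TaxonomyTable.from_dict(lineages)

    metadata = _generate_metadata(rng, sample_ids, group_of, config)
    return table, taxonomy, metadata


def _generate_metadata(rng, sample_ids, group_of, config: CohortConfig) -> SampleMetadata:
    grade = np.array([GROUP_LEVELS.index(g) for g in group_of])
    n = len(sample_ids)
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    df["group"] = group_of
    df["gender"] = np.where(rng.random(n) < 0.65, "male", "female")
    df["gestational_age"] = np.round(
        rng.normal(30.6 + config.gestational_age_slope * grade, 1.7), 1
    )
    df["birth_weight"] = np.round(
        rng.normal(1500.0 + config.birth_weight_slope * grade, 250.0), 0
    )
    df["delivery_mode"] = np.where(
        rng.random(n) < 0.50 + 0.08 * grade, "cesarean", "vaginal"
    )
    df["antibiotic_type"] = np.where(
        rng.random(n) < 0.30 + 0.15 * grade, "combination", "monotherapy"
    )
    df["ACS"] = (rng.random(n) < 0.7).astype(int)
    df["chorioamnionitis"] = (rng.random(n) < 0.15 + 0.05 * grade).astype(int)
    df["MSF"] = (rng.random(n) < 0.10).astype(int)
    df["EUGR"] = (rng.random(n) < 0.20 + 0.10 * grade).astype(int)
    df["intrauterine_distress"] = (rng.random(n) < 0.12 + 0.04 * grade).astype(int)
    df["length_of_stay"] = np.maximum(
        7, np.round(rng.normal(45.0 + 8.0 * grade, 10.0))
    ).astype(int)
    return SampleMetadata(df)


def generate_null_cohort(n_samples: int, n_taxa: int, depth: int, seed: int,
                         basis_log_sd: float = 1.0, basis_log_mean_sd: float = 0.0,
                         dominant_frac: float | None = None) -> CountTable:
    """Counts from *independent* log-normal basis abundances (no correlation).

    The calibration fixture for type-I-error and spurious-correlation tests.
    ``dominant_frac`` plants one taxon at roughly that mean relative abundance
    (e.g. 0.8) to exercise the closure-induced spurious correlations that
    compositionally robust methods must suppress.
    """
    for name, v in (("n_samples", n_samples), ("n_taxa", n_taxa), ("depth", depth)):
        if v <= 0:
            raise ConfigError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, basis_log_mean_sd, size=n_taxa)
    if dominant_frac is not None:
        mu[0] = np.log(dominant_frac / (1 - dominant_frac) * (n_taxa - 1)) + mu[1:].mean()
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        x = mu + basis_log_sd * rng.standard_normal(n_taxa)
        basis = np.exp(x - x.max())
        counts[i] = rng.multinomial(depth, basis / basis.sum())
    return CountTable(
        [f"S{i + 1}" for i in range(n_samples)],
        [f"ASV_{j + 1}" for j in range(n_taxa)],
        counts,
    )
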