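"""Count-table filtering and normalisation.

The default pipeline order is: singleton removal, organelle removal,
rarefaction (for diversity analyses), then the joint abundance/prevalence
filter ahead of network inference.  Each filter is idempotent.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .io import CountTable, TaxonomyTable, ValidationError

log = logging.getLogger(__name__)

#: Lineage substrings marking organelle contaminants (case-insensitive).
ORGANELLE_MARKERS = ("mitochondria", "chloroplast")


def remove_singletons(table: CountTable) -> CountTable:
    """Drop ASVs whose total frequency across the whole table is exactly 1."""
    totals = table.counts.sum(axis=0)
    keep = [t for t, tot in zip(table.taxon_ids, totals) if tot != 1]
    return table.select_taxa(keep)


def remove_organelles(table: CountTable, taxonomy: TaxonomyTable) -> CountTable:
    """Drop ASVs classified as mitochondrial or chloroplast at any rank.

    A rank matches if it contains "mitochondria" or "chloroplast" as a
    case-insensitive substring.
    """
    keep = []
    for t in table.taxon_ids:
        if t not in taxonomy:
            raise ValidationError(f"taxon {t!r} missing from taxonomy")
        lineage = taxonomy.lineage(t)
        if not any(m in rank.lower() for rank in lineage for m in ORGANELLE_MARKERS):
            keep.append(t)
    return table.select_taxa(keep)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    depths = table.depths
    rows, kept = [], []
    for i, sid in enumerate(table.sample_ids):
        if depths[i] < depth:
            log.warning("dropping sample %s: depth %d < rarefaction depth %d",
                        sid, depths[i], depth)
            continue
        # multivariate hypergeometric == subsampling reads without replacement
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        kept.append(sid)
    if not kept:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return CountTable(kept, list(table.taxon_ids), np.array(rows, dtype=np.int64))


def abundance_prevalence_filter(table: CountTable, min_rel_total: float = 1e-4,
                                min_prev_frac: float = 0.05,
                                mode: str = "grand_total") -> CountTable:
    """Joint abundance + prevalence filter ahead of network inference.

    A taxon is retained iff BOTH hold:

    * abundance: taxon total / table grand total strictly greater than
      ``min_rel_total`` (default 0.01%).  With ``mode="per_sample_mean"`` the
      abundance clause instead uses the mean per-sample relative abundance.
    * prevalence: present (count > 0) in at least
      ``ceil(min_prev_frac * n_samples)`` samples (0.05 x 98 samples -> 5).
    """
    if mode not in ("grand_total", "per_sample_mean"):
        raise ValueError(f"unknown abundance mode {mode!r}")
    grand = table.counts.sum()
    if grand == 0:
        raise ValidationError("empty count table")
    if mode == "grand_total":
        rel = table.counts.sum(axis=0) / grand
    else:
        depths = table.depths.astype(float)
        rel = (table.counts / depths[:, None]).mean(axis=0)
    prevalence = (table.counts > 0).sum(axis=0)
    cutoff = math.ceil(min_prev_frac * table.n_samples)
    keep = [
        t for j, t in enumerate(table.taxon_ids)
        if rel[j] > min_rel_total and prevalence[j] >= cutoff
    ]
    if not keep:
        raise ValidationError(
            "abundance/prevalence filter removed every taxon; relax the thresholds"
        )
    return table.select_taxa(keep)


def relative_abundance(table: CountTable) -> np.ndarray:
    """Row-normalised fractions; every row sums to 1."""
    depths = table.depths
    if np.any(depths == 0):
        bad = table.sample_ids[int(np.argmax(depths == 0))]
        raise ValidationError(f"sample {bad!r} has zero depth")
    return table.counts / depths[:, None].astype(float)
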