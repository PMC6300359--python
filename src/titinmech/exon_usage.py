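"""Per-exon percent-spliced-in (PSI) analysis of the titin transcript.

Inclusion reads (IR) overlap an exon; exclusion reads (ER) are junction
reads upstream or downstream that support skipping it.  Both are
normalized by the number of read start positions that can produce them:

    IR_n = IR / (exon_length + read_length - 1)
    ER_n = ER / (read_length - 1)
    PSI  = 100 * IR_n / (IR_n + ER_n)

PSI is undefined (NaN, flagged) for exons with no informative coverage.
Exon counts are adjusted to gene counts (E^A = E * Gbar / G_sample)
before between-genotype testing, which removes per-sample differences in
overall transcript abundance while preserving within-sample exon ratios.

The PSI-weighted residue sum over the PEVK region,
sum_i (PSI_i / 100) * n_residues_i, is the average transcript size of the
PEVK spring segment and feeds the wormlike-chain contour length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

REGIONS = ("Z-disk", "tandem-Ig", "PEVK", "A-band", "M-band")

#: -log10(p) display cap used for p-value tracks.
NEG_LOG10_P_CAP = 6.0


@dataclass(frozen=True)
class ExonRecord:
    """Structural metadata for one exon of the transcript.

    ``exon_index`` uses human-orthologous numbering.  ``n_residues`` is the
    number of amino acids the exon encodes; ``length_nt`` its nucleotide
    length (codons may span junctions, so no divisibility is assumed).
    """

    exon_index: int
    region: str
    length_nt: int
    n_residues: int
    deleted_in_model: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidInputError(
                f"exon {self.exon_index}: unknown region {self.region!r}; "
                f"expected one of {REGIONS}"
            )
        if self.length_nt <= 0:
            raise InvalidInputError(
                f"exon {self.exon_index}: length_nt must be positive"
            )
        if self.n_residues < 0:
            raise InvalidInputError(
                f"exon {self.exon_index}: n_residues must be >= 0"
            )


@dataclass
class SampleCounts:
    """Per-exon inclusion/exclusion read counts for one sample.

    ``counts`` has columns ``exon_index``, ``inclusion_reads``,
    ``exclusion_reads`` with one row per annotated exon.
    """

    sample_id: str
    genotype: str
    muscle: str
    read_length: int
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.read_length < 2:
            raise InvalidInputError(
                f"sample {self.sample_id}: read_length must be >= 2 "
                "(exclusion normalization divides by read_length - 1)"
            )
        required = {"exon_index", "inclusion_reads", "exclusion_reads"}
        missing = required - set(self.counts.columns)
        if missing:
            raise InvalidInputError(
                f"sample {self.sample_id}: counts table missing columns {sorted(missing)}"
            )
        if self.counts["exon_index"].duplicated().any():
            dup = self.counts.loc[self.counts["exon_index"].duplicated(), "exon_index"]
            raise InvalidInputError(
                f"sample {self.sample_id}: duplicate exon_index {sorted(set(dup))}"
            )
        for col in ("inclusion_reads", "exclusion_reads"):
            if (self.counts[col] < 0).any():
                raise InvalidInputError(
                    f"sample {self.sample_id}: negative values in {col}"
                )


def annotation_frame(annotation: list[ExonRecord]) -> pd.DataFrame:
    """Annotation records as a DataFrame indexed like the counts tables."""
    idx = [e.exon_index for e in annotation]
    if len(set(idx)) != len(idx):
        raise InvalidInputError("duplicate exon_index in annotation")
    return pd.DataFrame(
        {
            "exon_index": idx,
            "region": [e.region for e in annotation],
            "length_nt": [e.length_nt for e in annotation],
            "n_residues": [e.n_residues for e in annotation],
            "deleted_in_model": [e.deleted_in_model for e in annotation],
        }
    )


def normalize_counts(
    inclusion_reads: float,
    exclusion_reads: float,
    length_nt: int,
    read_length: int,
) -> tuple[float, float]:
    """Length-normalize inclusion/exclusion counts to reads per position."""
    if read_length < 2:
        raise InvalidInputError("read_length must be >= 2")
    if length_nt < 1:
        raise InvalidInputError("exon length_nt must be >= 1")
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise InvalidInputError("read counts must be non-negative")
    ir_n = inclusion_reads / (length_nt + read_length - 1)
    er_n = exclusion_reads / (read_length - 1)
    return ir_n, er_n


def compute_psi(ir_n: float, er_n: float) -> float:
    """PSI percent from normalized counts; NaN when coverage is zero."""
    if ir_n < 0 or er_n < 0:
        raise InvalidInputError("normalized counts must be non-negative")
    total = ir_n + er_n
    if total == 0:
        return math.nan
    return 100.0 * ir_n / total


def psi_profile(sample: SampleCounts, annotation: list[ExonRecord]) -> pd.DataFrame:
    """Per-exon PSI table for one sample.

    Returns columns ``exon_index, region, ir_n, er_n, psi``; PSI is NaN for
    exons with zero informative coverage.
    """
    ann = annotation_frame(annotation)
    merged = ann.merge(sample.counts, on="exon_index", how="left", validate="1:1")
    if merged[["inclusion_reads", "exclusion_reads"]].isna().any().any():
        missing = merged.loc[merged["inclusion_reads"].isna(), "exon_index"]
        raise InvalidInputError(
            f"sample {sample.sample_id}: no counts for exons {sorted(missing)}"
        )
    ir_n = merged["inclusion_reads"] / (merged["length_nt"] + sample.read_length - 1)
    er_n = merged["exclusion_reads"] / (sample.read_length - 1)
    total = ir_n + er_n
    psi = np.where(total > 0, 100.0 * ir_n / total.where(total > 0, 1.0), np.nan)
    return pd.DataFrame(
        {
            "exon_index": merged["exon_index"],
            "region": merged["region"],
            "ir_n": ir_n,
            "er_n": er_n,
            "psi": psi,
        }
    )


def adjust_exon_counts(
    exon_count: float, gene_count: float, gene_mean_count: float
) -> float:
    """Adjust an exon count to the mean gene count: E^A = E * Gbar / G."""
    if gene_count <= 0:
        raise InvalidInputError("gene_count must be positive for adjustment")
    return exon_count * gene_mean_count / gene_count


def group_psi(
    samples: list[SampleCounts],
    annotation: list[ExonRecord],
    pooled: bool = False,
) -> pd.DataFrame:
    """Group-level PSI per exon.

    Default averages per-sample PSI values (missing values excluded), which
    matches per-sample error bars; ``pooled=True`` instead sums normalized
    counts over samples before forming PSI.
    """
    if not samples:
        raise InvalidInputError("at least one sample required")
    profiles = [psi_profile(s, annotation) for s in samples]
    base = profiles[0][["exon_index", "region"]].copy()
    if pooled:
        ir = sum(p["ir_n"].to_numpy() for p in profiles)
        er = sum(p["er_n"].to_numpy() for p in profiles)
        total = ir + er
        base["psi"] = np.where(total > 0, 100.0 * ir / np.where(total > 0, total, 1.0), np.nan)
        base["n_samples"] = len(samples)
    else:
        psis = np.column_stack([p["psi"].to_numpy() for p in profiles])
        with np.errstate(invalid="ignore"):
            base["psi"] = np.nanmean(psis, axis=1)
        base["n_samples"] = np.sum(~np.isnan(psis), axis=1)
    return base


def _adjusted_samples(samples: list[SampleCounts]) -> list[SampleCounts]:
    """Adjust each sample's exon counts to the mean total gene count."""
    totals = [
        float(s.counts["inclusion_reads"].sum() + s.counts["exclusion_reads"].sum())
        for s in samples
    ]
    if any(t <= 0 for t in totals):
        raise InvalidInputError("cannot adjust counts: a sample has zero total reads")
    gbar = float(np.mean(totals))
    out = []
    for s, g in zip(samples, totals):
        c = s.counts.copy()
        c["inclusion_reads"] = c["inclusion_reads"] * gbar / g
        c["exclusion_reads"] = c["exclusion_reads"] * gbar / g
        out.append(
            SampleCounts(
                sample_id=s.sample_id,
                genotype=s.genotype,
                muscle=s.muscle,
                read_length=s.read_length,
                counts=c,
            )
        )
    return out


def _pooled_test(ir_a, er_a, ir_b, er_b) -> float:
    """Two-sided p for equal inclusion proportion from a pooled 2x2 table.

    Chi-square without continuity correction when all expected counts are
    at least 5, Fisher's exact test otherwise (counts rounded to integers).
    """
    table = np.array([[ir_a, er_a], [ir_b, er_b]], dtype=float)
    if table.sum() <= 0 or table[0].sum() == 0 or table[1].sum() == 0:
        return math.nan
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0  # no variation in inclusion status
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() >= 5:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        _, p = stats.fisher_exact(np.round(table).astype(int))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _permutation_test(
    psi_a: np.ndarray, psi_b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided label-permutation p for a difference in group mean PSI.

    Exact enumeration when there are at most 10 samples in total; otherwise
    ``n_perm`` random assignments.  The observed assignment is always
    counted, so p is in (0, 1].
    """
    values = np.concatenate([psi_a, psi_b])
    n_a = len(psi_a)
    observed = abs(np.mean(psi_a) - np.mean(psi_b))
    n = len(values)
    total_mean = values.mean()

    def stat(idx_a: np.ndarray) -> float:
        m_a = values[idx_a].mean()
        m_b = (total_mean * n - m_a * n_a) / (n - n_a)
        return abs(m_a - m_b)

    if n <= 10:
        stats_all = [
            stat(np.array(c)) for c in itertools.combinations(range(n), n_a)
        ]
        stats_all = np.array(stats_all)
        return float(np.mean(stats_all >= observed - 1e-12))
    hits = 1  # observed assignment
    for _ in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        if stat(idx) >= observed - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def differential_exon_usage(
    group_a: list[SampleCounts],
    group_b: list[SampleCounts],
    annotation: list[ExonRecord],
    method: str = "pooled",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-exon PSI difference and two-sided p-value between two groups.

    ``delta_psi`` is mean PSI of group A minus mean PSI of group B, in
    percentage points.  ``method="pooled"`` (default) tests equality of the
    inclusion proportion on gene-count-adjusted counts pooled within each
    group; ``method="permutation"`` permutes sample labels over per-sample
    PSI values.  Exons with no informative coverage in a group get a NaN
    p-value (and NaN delta if PSI is undefined group-wide).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidInputError("each group needs at least 2 samples")
    if method not in ("pooled", "permutation"):
        raise InvalidInputError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    adj_a = _adjusted_samples(group_a)
    adj_b = _adjusted_samples(group_b)
    prof_a = [psi_profile(s, annotation) for s in adj_a]
    prof_b = [psi_profile(s, annotation) for s in adj_b]

    exon_index = prof_a[0]["exon_index"].to_numpy()
    psi_a = np.column_stack([p["psi"].to_numpy() for p in prof_a])
    psi_b = np.column_stack([p["psi"].to_numpy() for p in prof_b])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        mean_a = np.nanmean(psi_a, axis=1)
        mean_b = np.nanmean(psi_b, axis=1)
    delta = mean_a - mean_b

    ir_a = np.column_stack([p["ir_n"].to_numpy() for p in prof_a]).sum(axis=1)
    er_a = np.column_stack([p["er_n"].to_numpy() for p in prof_a]).sum(axis=1)
    ir_b = np.column_stack([p["ir_n"].to_numpy() for p in prof_b]).sum(axis=1)
    er_b = np.column_stack([p["er_n"].to_numpy() for p in prof_b]).sum(axis=1)

    pvals = np.full(len(exon_index), np.nan)
    for i in range(len(exon_index)):
        a_cov = ir_a[i] + er_a[i] > 0
        b_cov = ir_b[i] + er_b[i] > 0
        if not (a_cov and b_cov):
            continue
        if method == "pooled":
            # scale normalized (fractional) counts back to read-count
            # magnitude so the chi-square reflects the sequencing depth
            pvals[i] = _pooled_test(
                ir_a[i] * (group_a[0].read_length - 1),
                er_a[i] * (group_a[0].read_length - 1),
                ir_b[i] * (group_b[0].read_length - 1),
                er_b[i] * (group_b[0].read_length - 1),
            )
        else:
            va = psi_a[i][~np.isnan(psi_a[i])]
            vb = psi_b[i][~np.isnan(psi_b[i])]
            if len(va) >= 2 and len(vb) >= 2:
                pvals[i] = _permutation_test(va, vb, n_perm, rng)
    return pd.DataFrame(
        {
            "exon_index": exon_index,
            "region": prof_a[0]["region"],
            "psi_a": mean_a,
            "psi_b": mean_b,
            "delta_psi": delta,
            "p_value": pvals,
            "neg_log10_p": neg_log10_p(pvals),
        }
    )


def neg_log10_p(p) -> np.ndarray:
    """-log10(p) capped at 6 for display tracks."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.minimum(-np.log10(p), NEG_LOG10_P_CAP)
    return out


def pevk_residue_count(
    psi: pd.DataFrame | dict,
    annotation: list[ExonRecord],
    region: str = "PEVK",
) -> float:
    """PSI-weighted residue count of a transcript region.

    ``psi`` maps exon_index to PSI percent (dict, or a DataFrame with
    ``exon_index``/``psi`` columns).  Every exon of the region must have a
    defined PSI; a missing or NaN PSI raises, naming the exon.
    """
    if isinstance(psi, pd.DataFrame):
        psi_map = dict(zip(psi["exon_index"], psi["psi"]))
    else:
        psi_map = dict(psi)
    total = 0.0
    for exon in annotation:
        if exon.region != region:
            continue
        if exon.exon_index not in psi_map:
            raise InvalidInputError(
                f"no PSI value for {region} exon {exon.exon_index}"
            )
        value = psi_map[exon.exon_index]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise InvalidInputError(
                f"PSI undefined (no coverage) for {region} exon {exon.exon_index}"
            )
        if not 0.0 <= value <= 100.0 + 1e-9:
            raise InvalidInputError(
                f"PSI out of [0, 100] for exon {exon.exon_index}: {value}"
            )
        total += (value / 100.0) * exon.n_residues
    return total
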