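"""Variant and sample filters that turn raw genotypes into an analysis panel.

The pipeline applies, in a fixed order: variant-level hygiene (autosomes
only, true SNPs only, strand-ambiguous A/T and G/C pairs removed,
duplicated ids deduplicated, allele conflicts across merged sources
dropped), a one-sided Hardy-Weinberg exact test for heterozygote excess,
missingness thresholds, relatedness pruning, PCA-loading outlier window
pruning, and per-locale downsampling.  Every rule reports exactly how many
records it removed so counts reconcile with matrix shapes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .stats import pca_decompose

AUTOSOMES = {str(i) for i in range(1, 23)}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("G", "C"))}
_BASES = {"A", "C", "G", "T"}

# Default thresholds for the panel-preparation pipeline.
HWE_ALPHA = 1e-5
SNP_MISS = 0.01
IND_MISS = 0.05
REL_CUTOFF = 0.6
PC_OUTLIER_Z = 5.0
PC_OUTLIER_WINDOW_BP = 200_000
MAX_PER_LOCALE = 50


@dataclasses.dataclass
class FilterReport:
    """Counts removed per rule, plus the thresholds that were applied."""

    removed: dict[str, int] = dataclasses.field(default_factory=dict)
    thresholds: dict[str, float] = dataclasses.field(default_factory=dict)

    def add(self, rule: str, count: int) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + int(count)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"removed": self.removed, "thresholds": self.thresholds}, indent=2))

    def total(self, rules: list[str]) -> int:
        return sum(self.removed.get(r, 0) for r in rules)


def hwe_exact_het_excess(n_hom_ref: int, n_het: int, n_hom_alt: int,
                         mid_p: bool = True) -> float:
    """One-sided exact Hardy-Weinberg test for heterozygote EXCESS.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Levene/Haldane distribution) and returns the
    one-sided (mid-)p-value for observing at least the given number of
    heterozygotes.  Heterozygote excess is the artifactual failure mode of
    merged strand errors; a deficit is expected under population structure
    and is deliberately not tested.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # enumerate heterozygote counts with the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probabilities of the Levene distribution
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln((n_common - hets) / 2 + 1)
    )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    obs = n_het
    above = w[hets > obs].sum()
    at = w[hets == obs].sum()
    return float(above + (0.5 * at if mid_p else at))


def filter_variants(g: GenotypeMatrix, hwe_alpha: float = HWE_ALPHA,
                    snp_miss: float = SNP_MISS,
                    ind_miss: float = IND_MISS) -> tuple[GenotypeMatrix, FilterReport]:
    """Variant-level filter cascade, in fixed order.

    1. drop non-autosomal records and non-SNP alleles;
    2. drop strand-ambiguous A/T and G/C pairs;
    3. deduplicate repeated SNP ids (same alleles: keep first; conflicting
       alternative alleles across merged sources: drop all copies);
    4. one-sided heterozygote-excess HWE exact test at ``hwe_alpha``;
    5. SNP missingness > ``snp_miss``, then individual missingness >
       ``ind_miss``.
    """
    if not {"chrom", "pos", "a1", "a2", "snp_id"} <= set(g.snps.columns):
        raise ValueError("SNP metadata (chrom, pos, alleles, id) required")
    report = FilterReport(thresholds={
        "hwe_alpha": hwe_alpha, "snp_miss": snp_miss, "ind_miss": ind_miss})
    snps = g.snps
    keep = np.ones(g.n_snps, dtype=bool)

    chrom = snps["chrom"].astype(str).str.removeprefix("chr")
    non_auto = ~chrom.isin(AUTOSOMES).to_numpy()
    a1 = snps["a1"].astype(str).str.upper()
    a2 = snps["a2"].astype(str).str.upper()
    non_snp = ~(a1.isin(_BASES) & a2.isin(_BASES)).to_numpy() & ~non_auto
    report.add("non_autosomal", non_auto.sum())
    report.add("non_snp", non_snp.sum())
    keep &= ~(non_auto | non_snp)

    pairs = [frozenset((x, y)) for x, y in zip(a1, a2)]
    ambiguous = np.array([p in _AMBIGUOUS for p in pairs]) & keep
    report.add("ambiguous_strand", ambiguous.sum())
    keep &= ~ambiguous

    # duplicate ids: same alleles -> keep the first copy; different
    # alternative alleles across sources -> drop every copy
    dup_removed = 0
    mismatch_removed = 0
    ids = snps["snp_id"].to_numpy()
    by_id: dict[str, list[int]] = {}
    for i in np.flatnonzero(keep):
        by_id.setdefault(ids[i], []).append(i)
    for sid, rows in by_id.items():
        if len(rows) == 1:
            continue
        allele_sets = {(a1.iloc[i], a2.iloc[i]) for i in rows}
        if len(allele_sets) > 1:
            for i in rows:
                keep[i] = False
            mismatch_removed += len(rows)
        else:
            for i in rows[1:]:
                keep[i] = False
            dup_removed += len(rows) - 1
    report.add("duplicate_id", dup_removed)
    report.add("allele_mismatch", mismatch_removed)

    calls = g.calls
    hwe_fail = np.zeros(g.n_snps, dtype=bool)
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        counts = ((col == 0).sum(), (col == 1).sum(), (col == 2).sum())
        if hwe_exact_het_excess(*counts) < hwe_alpha:
            hwe_fail[j] = True
    report.add("hwe_fail", hwe_fail.sum())
    keep &= ~hwe_fail

    snp_missing = (calls == -1).mean(axis=0) > snp_miss
    snp_missing &= keep
    report.add("snp_missingness", snp_missing.sum())
    keep &= ~snp_missing

    out = g.take_snps(np.flatnonzero(keep))
    ind_bad = out.missing_rate_per_sample() > ind_miss
    report.add("ind_missingness", ind_bad.sum())
    out = out.take_samples(np.flatnonzero(~ind_bad))
    if out.n_snps == 0 or out.n_samples == 0:
        raise ValueError("filtering removed the entire panel")
    return out, report


def relatedness_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Standardized genotype cross-product relatedness.

    Per SNP, calls are centered by the sample mean and scaled by the sample
    standard deviation; entry (i, j) averages z_i * z_j over loci
    non-missing in both individuals.
    """
    X = g.calls.astype(float)
    miss = g.calls == -1
    X[miss] = np.nan
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    informative = sd > 0
    Z = (X - mean[None, :]) / np.where(informative, sd, 1.0)[None, :]
    Z[:, ~informative] = np.nan
    obs = ~np.isnan(Z)
    Zf = np.where(obs, Z, 0.0)
    num = Zf @ Zf.T
    den = obs.astype(float) @ obs.astype(float).T
    den[den == 0] = np.nan
    return num / den


def relatedness_prune(g: GenotypeMatrix, cutoff: float = REL_CUTOFF
                      ) -> tuple[np.ndarray, FilterReport]:
    """Greedy pruning of pairs whose relatedness exceeds ``cutoff``.

    From the currently worst pair, the member with more missing data is
    removed (ties: the larger sample index), until no pair exceeds the
    cutoff.  Returns the positional indices of kept samples.
    """
    if not (0 < cutoff <= 2):
        raise ValueError("cutoff must be in (0, 2]")
    if g.n_samples < 2 or g.n_snps < 50:
        raise ValueError("need >= 2 individuals and >= 50 SNPs")
    rel = relatedness_matrix(g)
    np.fill_diagonal(rel, 0.0)
    missing = (g.calls == -1).sum(axis=1)
    active = np.ones(g.n_samples, dtype=bool)
    removed = 0
    while True:
        sub = np.where(np.outer(active, active), rel, -np.inf)
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        if not (sub[i, j] > cutoff):
            break
        if missing[i] > missing[j]:
            drop = i
        elif missing[j] > missing[i]:
            drop = j
        else:
            drop = max(i, j)
        active[drop] = False
        removed += 1
    report = FilterReport(removed={"related_removed": removed},
                          thresholds={"rel_cutoff": cutoff})
    return np.flatnonzero(active), report


def loading_outlier_prune(g: GenotypeMatrix, n_pcs: int = 10,
                          z_thresh: float = PC_OUTLIER_Z,
                          window_bp: int = PC_OUTLIER_WINDOW_BP
                          ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove windows around SNPs with outlying PC loadings.

    Loadings on each of the first ``n_pcs`` PCs are normalized by their
    standard deviation (outlier_score = loading / sd); any SNP scoring
    ``|outlier_score| > z_thresh`` on any PC marks a ±``window_bp``/2
    interval on its chromosome, and all SNPs in marked intervals are
    removed.  This targets structural variants whose LD blocks dominate
    single PCs.
    """
    if n_pcs > min(g.n_samples - 1, g.n_snps):
        raise ValueError("n_pcs exceeds the rank of the panel")
    for chrom, sub in g.snps.groupby("chrom"):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"positions not sorted within chromosome {chrom}")
    pca = pca_decompose(g, n_pcs)
    sd = pca.loadings.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    score = pca.loadings / sd[None, :]
    outlier = (np.abs(score) > z_thresh).any(axis=1)
    half = window_bp // 2
    remove = np.zeros(g.n_snps, dtype=bool)
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    for i in np.flatnonzero(outlier):
        window = (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= half)
        remove |= window
    report = FilterReport(
        removed={"loading_outlier_snps": int(remove.sum())},
        thresholds={"z_thresh": z_thresh, "window_bp": window_bp, "n_pcs": n_pcs})
    return g.take_snps(np.flatnonzero(~remove)), report


def locale_keys(samples: pd.DataFrame, decimals: int = 2) -> np.ndarray:
    """Locale key per sample: coordinates rounded to ``decimals`` places."""
    lon = samples["lon"].round(decimals)
    lat = samples["lat"].round(decimals)
    return np.array([f"{a}:{b}" for a, b in zip(lon, lat)])


def downsample_locales(locales: np.ndarray, max_per_locale: int = MAX_PER_LOCALE,
                       seed: int = 0) -> np.ndarray:
    """Cap each locale at ``max_per_locale`` samples (uniform without
    replacement, seeded).  Returns kept positional indices, sorted."""
    if max_per_locale < 1:
        raise ValueError("max_per_locale must be >= 1")
    locales = np.asarray(locales)
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for key in pd.unique(locales):
        idx = np.flatnonzero(locales == key)
        if len(idx) > max_per_locale:
            idx = rng.choice(idx, size=max_per_locale, replace=False)
        kept.append(idx)
    return np.sort(np.concatenate(kept))
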