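"""Marker quality statistics and subset selection.

Covers Hardy-Weinberg testing (chi-square, with an exact mid-p option),
pairwise composite linkage disequilibrium (squared dosage correlation),
per-locus FST between the two breeding lines (Nei G_ST-style by default,
Weir-Cockerham theta as an option), private-allele detection, and the
subset-selection workflow: a diversity subset of unlinked loci in HWE and a
line-discrimination subset of loci above an FST threshold, both estimated on
a first-degree-relative-free individual set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import GenotypeMatrix, MarkerDef, PanelError, Pedigree

DEFAULT_FST_MIN = 0.075
DEFAULT_HWE_ALPHA = 0.05
DEFAULT_LD_MAX = 0.8
DEFAULT_MIN_CALLED = 5
DEFAULT_LD_MIN_SHARED = 20


def remove_first_degree(gm: GenotypeMatrix, pedigree: Pedigree) -> GenotypeMatrix:
    """Drop offspring whose both parents are genotyped.

    This is the relative filter used before allele-frequency estimation: when
    both parents of an individual are present in the genotype set, the
    offspring is removed so family structure does not bias frequencies.
    """
    present = set(gm.individuals)
    drop = set()
    for iid in gm.individuals:
        if iid not in pedigree.table.index:
            continue
        sire, dam = pedigree.parents(iid)
        if sire in present and dam in present:
            drop.add(iid)
    keep = [i for i in gm.individuals if i not in drop]
    return GenotypeMatrix(gm.genotypes.loc[keep].copy(), gm.labels.loc[keep].copy())


def _genotype_counts(dosage_col: pd.Series) -> tuple:
    col = dosage_col.dropna()
    n_aa = int((col == 0).sum())
    n_ab = int((col == 1).sum())
    n_bb = int((col == 2).sum())
    return n_aa, n_ab, n_bb


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple:
    """Chi-square HWE test (1 df) from genotype counts; (stat, p)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return np.nan, np.nan
    q = (n_ab + 2 * n_bb) / (2 * n)
    p = 1 - q
    if p == 0 or q == 0:
        return np.nan, np.nan  # monomorphic: test undefined
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))


def hwe_exact(n_aa: int, n_ab: int, n_bb: int, midp: bool = True) -> float:
    """Exact HWE test (conditional on allele counts), optionally mid-p."""
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb
    n_b = min(n_b, 2 * n - n_b)  # rarer allele count
    if n == 0 or n_b == 0:
        return np.nan
    # probabilities of every heterozygote count with the same allele counts
    hets = np.arange(n_b % 2, n_b + 1, 2)
    from scipy.special import gammaln

    logp = []
    for h in hets:
        rare_hom = (n_b - h) // 2
        common_hom = n - h - rare_hom
        lp = (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            + h * np.log(2)
            + gammaln(n_b + 1)
            + gammaln(2 * n - n_b + 1)
            - gammaln(2 * n + 1)
        )
        logp.append(lp)
    probs = np.exp(np.array(logp) - max(logp))
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0] if (hets == n_ab).any() else 0.0
    tail = probs[probs <= p_obs + 1e-12].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(1.0, tail))


def fst_nei(p1: float, p2: float) -> float:
    """Per-locus Nei-style FST = (H_T - H_S) / H_T, unweighted two groups."""
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    hs = (h1 + h2) / 2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    if ht == 0:
        return np.nan
    return (ht - hs) / ht

def fst_weir_cockerham(p1: float, p2: float, n1: int, n2: int) -> float:
    """Per-locus Weir-Cockerham theta for two groups (allele-frequency form,
    no within-individual component). Available as an estimator option."""
    r = 2
    nbar = (n1 + n2) / 2
    if nbar <= 1:
        return np.nan
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    denom = a + b
    if denom == 0:
        return np.nan
    return a / denom


@dataclass
class LdMatrix:
    r2: pd.DataFrame  # marker x marker squared dosage correlation
    counts: pd.DataFrame  # shared complete individuals per pair
    min_shared: int

    def violating_pairs(self, ld_max: float) -> list:
        out = []
        cols = list(self.r2.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                v = self.r2.loc[a, b]
                if pd.notna(v) and v > ld_max:
                    out.append((a, b, float(v)))
        return out


def ld_r2(gm: GenotypeMatrix, markers: list,
          min_shared: int = DEFAULT_LD_MIN_SHARED) -> LdMatrix:
    """Composite LD: squared Pearson correlation of allele-dosage vectors.

    Computed pairwise over individuals called at both loci (no phasing).
    Pairs with fewer than ``min_shared`` shared complete individuals, or with
    a zero-variance dosage at either locus, are undefined (NaN).
    """
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    dos = gm.dosage(auto)
    r = dos.corr(min_periods=min_shared)
    r2 = r ** 2
    called = dos.notna().astype(int)
    counts = called.T @ called
    return LdMatrix(r2, counts, min_shared)


@dataclass
class SelectionResult:
    locus_stats: pd.DataFrame
    diversity_subset: list  # unlinked loci in HWE
    line_subset: list  # loci with FST >= threshold
    private_alleles: pd.DataFrame  # marker, group, allele
    ld: LdMatrix
    reference_individuals: list  # the relative-filtered set used for freqs


def locus_statistics(gm: GenotypeMatrix, markers: list,
                     min_called: int = DEFAULT_MIN_CALLED,
                     fst_estimator: str = "nei",
                     exact_hwe: bool = False) -> pd.DataFrame:
    """Per-locus genotype counts, frequencies, H_O/H_E, HWE test and line FST."""
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    lines = gm.labels["line"]
    groups = [g for g in ("LL", "LC") if (lines == g).any()]
    dos = gm.dosage(auto)
    rows = {}
    for m in auto:
        col = dos[m.marker_id]
        n_aa, n_ab, n_bb = _genotype_counts(col)
        n = n_aa + n_ab + n_bb
        q = (n_ab + 2 * n_bb) / (2 * n) if n else np.nan
        h_o = n_ab / n if n else np.nan
        h_e = 2 * q * (1 - q) if n else np.nan
        if n >= min_called and 0 < q < 1:
            if exact_hwe:
                stat, pval = np.nan, hwe_exact(n_aa, n_ab, n_bb)
            else:
                stat, pval = hwe_chisq(n_aa, n_ab, n_bb)
        else:
            stat, pval = np.nan, np.nan
        rec = {"n_aa": n_aa, "n_ab": n_ab, "n_bb": n_bb, "n": n,
               "freq_b": q, "h_o": h_o, "h_e": h_e,
               "hwe_chisq": stat, "hwe_p": pval,
               "monomorphic": not (0 < q < 1) if n else True}
        if len(groups) == 2:
            gq, gn = {}, {}
            for gname in groups:
                sub = col[lines == gname].dropna()
                gn[gname] = len(sub)
                gq[gname] = float(sub.sum()) / (2 * len(sub)) if len(sub) else np.nan
            if fst_estimator == "wc":
                rec["fst"] = fst_weir_cockerham(gq[groups[0]], gq[groups[1]],
                                                gn[groups[0]], gn[groups[1]])
            else:
                rec["fst"] = fst_nei(gq[groups[0]], gq[groups[1]])
            for gname in groups:
                rec[f"freq_b_{gname}"] = gq[gname]
        rows[m.marker_id] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def private_alleles(gm: GenotypeMatrix, markers: list) -> pd.DataFrame:
    """Alleles with nonzero count in exactly one breeding line."""
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    lines = gm.labels["line"]
    groups = sorted(set(lines) - {"U"})
    dos = gm.dosage(auto)
    rows = []
    for m in auto:
        for allele, count_fn in ((m.allele_a, lambda d: 2 * (d == 0).sum() + (d == 1).sum()),
                                 (m.allele_b, lambda d: 2 * (d == 2).sum() + (d == 1).sum())):
            carriers = []
            for gname in groups:
                sub = dos[m.marker_id][lines == gname].dropna()
                if len(sub) and count_fn(sub) > 0:
                    carriers.append(gname)
            if len(carriers) == 1:
                rows.append({"marker_id": m.marker_id, "allele": allele,
                             "group": carriers[0]})
    return pd.DataFrame(rows, columns=["marker_id", "allele", "group"])


def rank_and_select(gm: GenotypeMatrix, markers: list,
                    pedigree: Pedigree | None = None,
                    fst_min: float = DEFAULT_FST_MIN,
                    hwe_alpha: float = DEFAULT_HWE_ALPHA,
                    bonferroni: bool = True,
                    ld_max: float = DEFAULT_LD_MAX,
                    min_called: int = DEFAULT_MIN_CALLED,
                    ld_min_shared: int = DEFAULT_LD_MIN_SHARED,
                    fst_estimator: str = "nei") -> SelectionResult:
    """Reproduce the marker-subset workflow.

    (a) diversity subset: polymorphic autosomal loci passing HWE at
    ``hwe_alpha`` (Bonferroni-corrected across tested loci by default) with
    greedy LD pruning (the higher-mean-R2 locus of each violating pair is
    dropped); (b) line subset: loci with per-locus FST >= ``fst_min``;
    (c) private alleles per line. Frequencies are estimated on the
    first-degree-relative-free individual set when a pedigree is supplied.
    """
    lines = gm.labels["line"]
    for gname in sorted(set(lines) - {"U"}):
        if (lines == gname).sum() < 2:
            raise PanelError(f"group {gname} has fewer than 2 individuals")
    ref = remove_first_degree(gm, pedigree) if pedigree is not None else gm
    stats_df = locus_statistics(ref, markers, min_called=min_called,
                                fst_estimator=fst_estimator)

    tested = stats_df["hwe_p"].notna()
    alpha = hwe_alpha / max(1, int(tested.sum())) if bonferroni else hwe_alpha
    pass_hwe = stats_df.index[(~stats_df["monomorphic"]) & (stats_df["hwe_p"].isna() | (stats_df["hwe_p"] >= alpha))]
    pass_hwe = [m for m in pass_hwe if not stats_df.loc[m, "monomorphic"]]

    by_id = {m.marker_id: m for m in markers}
    ld = ld_r2(ref.restrict([by_id[m] for m in pass_hwe]), [by_id[m] for m in pass_hwe],
               min_shared=ld_min_shared)
    keep = list(pass_hwe)
    while True:
        viol = [(a, b, v) for a, b, v in ld.violating_pairs(ld_max)
                if a in keep and b in keep]
        if not viol:
            break
        a, b, _ = max(viol, key=lambda t: t[2])
        mean_r2 = ld.r2.loc[[a, b], keep].mean(axis=1)
        keep.remove(a if mean_r2[a] >= mean_r2[b] else b)
    diversity_subset = [m for m in pass_hwe if m in keep]

    if "fst" in stats_df.columns:
        line_subset = list(stats_df.index[stats_df["fst"].fillna(-1) >= fst_min])
    else:
        line_subset = []
    priv = private_alleles(ref, markers)
    return SelectionResult(stats_df, diversity_subset, line_subset, priv, ld,
                           ref.individuals)
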