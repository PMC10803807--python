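"""Molecular and pedigree-based genetic diversity, side by side.

Molecular columns: observed heterozygosity, Nei's unbiased within-group
expected heterozygosity (H_S / uH_E), total expected heterozygosity H_T from
unweighted mean allele frequencies, rarefied allelic richness, and the
hierarchical F-statistics in two averaging modes (arithmetic mean of
per-locus values, and values recomputed from locus-averaged H's, under which
the identity (1-F_IT) = (1-F_IS)(1-F_ST) holds exactly). Standard errors are
delete-one-locus jackknives.

Pedigree columns: coancestry by the tabular method, inbreeding, gene
diversity of the living gene pool from mean kinship and from Monte-Carlo
gene drop, founder contributions, and pedigree F-statistics from mean
inbreeding and within/overall mean coancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel_io import GenotypeMatrix, PanelError, Pedigree

DEFAULT_GENE_DROP_ITERATIONS = 1000


# ---------------------------------------------------------------------------
# molecular diversity


def _per_locus_stats(dos: pd.DataFrame, groups: pd.Series, group_names: list):
    """Per-locus per-group n, allele-b freq, H_O and unbiased expected het."""
    out = {}
    for mid in dos.columns:
        rec = {}
        for g in group_names:
            col = dos[mid][groups == g].dropna() if g != "__total__" else dos[mid].dropna()
            n = len(col)
            if n == 0:
                rec[g] = (0, np.nan, np.nan, np.nan)
                continue
            q = float(col.sum()) / (2 * n)
            h_o = float((col == 1).mean())
            h_exp = 1 - (q * q + (1 - q) ** 2)
            uh = (2 * n / (2 * n - 1)) * h_exp if n > 1 else np.nan
            rec[g] = (n, q, h_o, uh)
        out[mid] = rec
    return out


def _rarefied_richness(dos: pd.DataFrame, groups: pd.Series, group_names: list) -> dict:
    """Allelic richness rarefied to the smallest group's gene-copy count.

    AR = sum over alleles of 1 - C(2N - N_i, g) / C(2N, g), averaged over
    loci; monomorphic loci contribute 1.
    """

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    ar = {}
    for g in group_names:
        per_locus = []
        for mid in dos.columns:
            col = dos[mid][groups == g].dropna() if g != "__total__" else dos[mid].dropna()
            n2 = 2 * len(col)
            if n2 == 0:
                continue
            # rarefaction size: smallest per-locus gene-copy count across real groups
            sizes = []
            for gg in group_names:
                if gg == "__total__":
                    continue
                cc = dos[mid][groups == gg].dropna()
                if len(cc):
                    sizes.append(2 * len(cc))
            gsize = min(sizes) if sizes else n2
            gsize = min(gsize, n2)
            nb = int(round(float(col.sum())))
            na = n2 - nb
            val = 0.0
            for cnt in (na, nb):
                if cnt == 0:
                    continue
                if n2 - cnt < gsize:
                    val += 1.0
                else:
                    val += 1.0 - np.exp(log_comb(n2 - cnt, gsize) - log_comb(n2, gsize))
            per_locus.append(val)
        ar[g] = float(np.mean(per_locus)) if per_locus else np.nan
    return ar


def _fstats_from_h(h_o, h_s, h_t):
    fis = 1 - h_o / h_s if h_s else np.nan
    fst = (h_t - h_s) / h_t if h_t else np.nan
    fit = 1 - h_o / h_t if h_t else np.nan
    return fis, fst, fit


@dataclass
class DiversityTable:
    table: pd.DataFrame  # rows: total + per line; molecular (+ pedigree) columns
    per_locus: pd.DataFrame
    notes: dict


def molecular_diversity(gm: GenotypeMatrix, markers: list,
                        group_col: str = "line",
                        nei_chesser: bool = False) -> DiversityTable:
    """Heterozygosities, allelic richness and two-mode F-statistics.

    F-statistics need >= 2 groups and are reported on the ``total`` row; loci
    monomorphic across all groups are excluded from them with a note.
    ``nei_chesser`` applies the small-sample correction to H_T.
    """
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    dos = gm.dosage(auto)
    groups = gm.labels[group_col]
    group_names = sorted(set(groups) - {"U"})
    for g in group_names:
        if (groups == g).sum() < 2:
            raise PanelError(f"group {g} has fewer than 2 individuals")
    stats = _per_locus_stats(dos, groups, group_names + ["__total__"])

    # per-locus hierarchical components over the real groups
    loci = []
    for mid, rec in stats.items():
        ns = [rec[g][0] for g in group_names]
        if any(n == 0 for n in ns):
            continue
        qs = np.array([rec[g][1] for g in group_names])
        h_os = np.array([rec[g][2] for g in group_names])
        uhs = np.array([rec[g][3] for g in group_names])
        h_o = float(h_os.mean())
        h_s = float(uhs.mean())
        qbar = float(qs.mean())
        h_t = 1 - (qbar ** 2 + (1 - qbar) ** 2)
        if nei_chesser:
            n_harm = len(ns) / np.sum([1 / n for n in ns])
            h_t = h_t + h_s / (2 * n_harm * len(group_names))
        mono = (qs == 0).all() or (qs == 1).all()
        loci.append({"marker_id": mid, "h_o": h_o, "h_s": h_s, "h_t": h_t,
                     "monomorphic": mono})
    pl = pd.DataFrame(loci).set_index("marker_id") if loci else pd.DataFrame()
    poly = pl[~pl["monomorphic"]] if len(pl) else pl

    def jackknife(values: np.ndarray) -> float:
        n = len(values)
        if n < 2:
            return np.nan
        loo = np.array([np.mean(np.delete(values, i)) for i in range(n)])
        return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))

    rows = {}
    ar = _rarefied_richness(dos, groups, group_names + ["__total__"])
    for g in group_names + ["__total__"]:
        name = "total" if g == "__total__" else g
        per = [(rec[g][0], rec[g][2], rec[g][3]) for rec in stats.values() if rec[g][0] > 0]
        n_ind = int(gm.labels.shape[0]) if g == "__total__" else int((groups == g).sum())
        h_o = float(np.mean([x[1] for x in per])) if per else np.nan
        uh_e = float(np.nanmean([x[2] for x in per])) if per else np.nan
        rows[name] = {"n": n_ind, "loci": len(per), "h_o": h_o, "uh_e": uh_e,
                      "ar": ar[g],
                      "h_o_se": jackknife(np.array([x[1] for x in per])),
                      "uh_e_se": jackknife(np.array([x[2] for x in per]))}

    notes = {"f_statistics": "unweighted group means; modes: arithmetic per-locus "
                             "(mode1) and from locus-averaged H (mode2)"}
    if len(group_names) >= 2 and len(poly):
        fis_l, fst_l, fit_l = zip(*(
            _fstats_from_h(r.h_o, r.h_s, r.h_t) for r in poly.itertuples()
        ))
        def nanmean(a):
            a = np.asarray(a, dtype=float)
            return float(np.nanmean(a)) if np.isfinite(a).any() else float("nan")

        t = rows["total"]
        t["fis_mode1"] = nanmean(fis_l)
        t["fst_mode1"] = nanmean(fst_l)
        t["fit_mode1"] = nanmean(fit_l)
        t["fis_se"] = jackknife(np.asarray(fis_l, dtype=float))
        t["fst_se"] = jackknife(np.asarray(fst_l, dtype=float))
        hbar_o, hbar_s, hbar_t = poly["h_o"].mean(), poly["h_s"].mean(), poly["h_t"].mean()
        fis2, fst2, fit2 = _fstats_from_h(hbar_o, hbar_s, hbar_t)
        t["fis_mode2"], t["fst_mode2"], t["fit_mode2"] = fis2, fst2, fit2
        t["h_s"], t["h_t"] = float(hbar_s), float(hbar_t)
        notes["excluded_monomorphic"] = int(pl["monomorphic"].sum())
    table = pd.DataFrame.from_dict(rows, orient="index")
    return DiversityTable(table, pl, notes)


# ---------------------------------------------------------------------------
# pedigree analytics


@dataclass
class KinshipMatrix:
    f: pd.DataFrame  # pairwise coancestry
    inbreeding: pd.Series  # F_i = f(sire_i, dam_i)


def pedigree_kinship(ped: Pedigree) -> KinshipMatrix:
    """Coancestry by the tabular-method recursion in topological order.

    f(i,j) = 0.5 [f(sire_i, j) + f(dam_i, j)] for j processed before i;
    f(i,i) = 0.5 (1 + f(sire_i, dam_i)). An unknown parent behaves as a
    unique non-inbred founder unrelated to everyone.
    """
    order = ped.topological_order()
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    f = np.zeros((n, n))
    inb = np.zeros(n)
    for iid in order:
        i = idx[iid]
        sire, dam = ped.parents(iid)
        si = idx.get(sire)
        di = idx.get(dam)
        fsd = f[si, di] if (si is not None and di is not None) else 0.0
        inb[i] = fsd
        f[i, i] = 0.5 * (1 + fsd)
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * f[si]
        if di is not None:
            row += 0.5 * f[di]
        row[i] = 0.5 * (1 + fsd)
        f[i, : i] = row[: i]
        f[: i, i] = row[: i]
    return KinshipMatrix(pd.DataFrame(f, index=order, columns=order),
                         pd.Series(inb, index=order))


@dataclass
class GeneDiversityResult:
    gd_kinship: float
    gd_genedrop: float
    gd_genedrop_se: float
    founder_contributions: pd.Series
    iterations: int


def gene_diversity(ped: Pedigree, living: set | list | None = None,
                   iterations: int = DEFAULT_GENE_DROP_ITERATIONS,
                   seed: int = 0,
                   kinship: KinshipMatrix | None = None) -> GeneDiversityResult:
    """Gene diversity of the living gene pool, two ways.

    GD_kinship = 1 - mean coancestry over all ordered pairs of living
    individuals (self-pairs included, the convention under which the two
    estimators agree in expectation). GD_genedrop labels each founder's two
    alleles uniquely, transmits them through the pedigree by Mendelian
    sampling, and averages 1 - sum q_a^2 over iterations. Also returns each
    founder's expected share of the living gene pool.
    """
    if living is None:
        living = set(ped.table.index[ped.table["alive"]])
    living = sorted(living)
    missing = [i for i in living if i not in ped.table.index]
    if missing:
        raise PanelError(f"living individuals absent from pedigree: {missing}")
    if iterations < 1:
        raise PanelError("iterations must be >= 1")
    if kinship is None:
        kinship = pedigree_kinship(ped)
    sub = kinship.f.loc[living, living].to_numpy()
    gd_kin = 1.0 - float(sub.mean())

    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    founders = ped.founders
    f_index = {fid: k for k, fid in enumerate(founders)}
    next_phantom = [len(founders)]
    alleles = {}
    for iid in order:
        sire, dam = ped.parents(iid)
        if sire is None and dam is None:
            k = f_index[iid]
            alleles[iid] = np.stack([np.full(iterations, 2 * k, dtype=np.int64),
                                     np.full(iterations, 2 * k + 1, dtype=np.int64)])
            continue
        pair = []
        for parent in (sire, dam):
            if parent is None:  # phantom founder: unique alleles, no inbreeding
                k = next_phantom[0]
                next_phantom[0] += 1
                arr = np.where(rng.random(iterations) < 0.5, 2 * k, 2 * k + 1)
            else:
                pa = alleles[parent]
                pick = rng.integers(2, size=iterations)
                arr = pa[pick, np.arange(iterations)]
            pair.append(arr)
        alleles[iid] = np.stack(pair)

    pool = np.concatenate([alleles[i] for i in living], axis=0)  # (2*n_living, iter)
    n_copies = pool.shape[0]
    gds = np.empty(iterations)
    for it in range(iterations):
        counts = np.bincount(pool[:, it])
        q = counts[counts > 0] / n_copies
        gds[it] = 1.0 - float(np.sum(q * q))
    gd_drop = float(gds.mean())
    gd_se = float(gds.std(ddof=1) / np.sqrt(iterations)) if iterations > 1 else np.nan

    # expected founder contributions by recursive averaging
    contrib = {}
    for iid in order:
        sire, dam = ped.parents(iid)
        if sire is None and dam is None:
            contrib[iid] = {iid: 1.0}
            continue
        c = {}
        for parent in (sire, dam):
            if parent is None:
                c["<unknown>"] = c.get("<unknown>", 0.0) + 0.5
            else:
                for fid, w in contrib[parent].items():
                    c[fid] = c.get(fid, 0.0) + 0.5 * w
        contrib[iid] = c
    totals = {}
    for iid in living:
        for fid, w in contrib[iid].items():
            totals[fid] = totals.get(fid, 0.0) + w / len(living)
    fc = pd.Series(totals).sort_values(ascending=False)
    return GeneDiversityResult(gd_kin, gd_drop, gd_se, fc, iterations)


def pedigree_f_stats(ped: Pedigree, living: set | list | None = None,
                     group_col: str = "line",
                     kinship: KinshipMatrix | None = None) -> dict:
    """Pedigree F-statistics from inbreeding and coancestry of the living.

    F_IS = (F - f_w) / (1 - f_w) with F the unweighted-group mean inbreeding
    and f_w the unweighted-group mean within-group pairwise coancestry
    (self-pairs excluded); F_ST = (f_w - f_all) / (1 - f_all) with f_all the
    overall mean pairwise coancestry; F_IT from the multiplicative identity.
    """
    if living is None:
        living = set(ped.table.index[ped.table["alive"]])
    living = sorted(living)
    groups = ped.table.loc[living, group_col]
    names = sorted(set(groups) - {"U"})
    if len(names) < 2:
        raise PanelError("pedigree F-statistics need >= 2 groups with living members")
    if kinship is None:
        kinship = pedigree_kinship(ped)
    f = kinship.f.loc[living, living].to_numpy()
    inb = kinship.inbreeding.loc[living]

    def off_diag_mean(mat):
        n = mat.shape[0]
        if n < 2:
            return np.nan
        return (mat.sum() - np.trace(mat)) / (n * (n - 1))

    fbar_g, fw_g, used = [], [], []
    for g in names:
        members = [i for i in living if groups[i] == g]
        if len(members) < 2:
            continue  # within-group coancestry undefined for singleton groups
        sel = kinship.f.loc[members, members].to_numpy()
        fbar_g.append(float(inb.loc[members].mean()))
        fw_g.append(off_diag_mean(sel))
        used.append(g)
    if len(used) < 2:
        raise PanelError("pedigree F-statistics need >= 2 groups with >= 2 living members")
    names = used
    fbar = float(np.mean(fbar_g))
    fw = float(np.mean(fw_g))
    fall = float(off_diag_mean(f))
    fis = (fbar - fw) / (1 - fw)
    fst = (fw - fall) / (1 - fall)
    fit = 1 - (1 - fis) * (1 - fst)
    return {"f_is": fis, "f_st": fst, "f_it": fit,
            "mean_inbreeding": fbar, "mean_within_kinship": fw,
            "mean_overall_kinship": fall, "groups": names,
            "weighting": "unweighted group means"}


def diversity_table(gm: GenotypeMatrix, markers: list, ped: Pedigree | None = None,
                    living: set | None = None, iterations: int = DEFAULT_GENE_DROP_ITERATIONS,
                    seed: int = 0) -> DiversityTable:
    """Molecular and pedigree diversity side by side (one call convenience)."""
    div = molecular_diversity(gm, markers)
    if ped is not None:
        kin = pedigree_kinship(ped)
        gd = gene_diversity(ped, living, iterations=iterations, seed=seed, kinship=kin)
        div.table.loc["total", "gd_kinship"] = gd.gd_kinship
        div.table.loc["total", "gd_genedrop"] = gd.gd_genedrop
        try:
            fs = pedigree_f_stats(ped, living, kinship=kin)
            div.table.loc["total", "fis_pedigree"] = fs["f_is"]
            div.table.loc["total", "fst_pedigree"] = fs["f_st"]
            div.table.loc["total", "fit_pedigree"] = fs["f_it"]
        except PanelError as exc:
            div.notes["pedigree_f_stats"] = str(exc)
        div.notes["pedigree_n"] = int(len(ped.table))
    return div
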