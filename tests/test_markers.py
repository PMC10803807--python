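import numpy as np
import pandas as pd
import pytest

from wisentpanel import markers as mks
from wisentpanel import panel_io as pio
from wisentpanel import simulate as sim
from wisentpanel.panel_io import NO_CALL, GenotypeMatrix, MarkerDef, PanelError


def _gm_from_dosage(dos, markers, lines=None):
    rows = []
    for r in dos:
        rows.append([markers[j].genotypes[int(d)] if not np.isnan(d) else NO_CALL
                     for j, d in enumerate(r)])
    genos = pd.DataFrame(rows, columns=[m.marker_id for m in markers],
                         index=[f"I{i}" for i in range(len(dos))])
    labels = pd.DataFrame({"group": "focal",
                           "line": lines if lines is not None else "U",
                           "sex": "U"}, index=genos.index)
    return GenotypeMatrix(genos, labels)


MKS = [MarkerDef(f"M{i}", "1", "A", "C") for i in range(4)]


def test_hwe_chisq_perfect_and_extreme():
    stat, p = mks.hwe_chisq(25, 50, 25)
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    # all homozygotes at p=q=0.5: chi-square equals n
    stat2, p2 = mks.hwe_chisq(50, 0, 50)
    assert stat2 == pytest.approx(100.0)
    assert p2 < 1e-20


def test_hwe_monomorphic_undefined():
    stat, p = mks.hwe_chisq(40, 0, 0)
    assert np.isnan(stat) and np.isnan(p)


def test_hwe_exact_matches_chisq_direction():
    # strong het deficit: both tests reject
    assert mks.hwe_exact(30, 5, 30) < 1e-6
    # perfect proportions: exact mid-p is large
    assert mks.hwe_exact(25, 50, 25) > 0.3


def test_hwe_type_i_error_rate():
    """Chi-square rejection rate under true HWE is close to alpha."""
    rng = np.random.default_rng(7)
    n, n_loci, alpha = 120, 600, 0.05
    rej = 0
    tested = 0
    for _ in range(n_loci):
        q = rng.uniform(0.2, 0.8)
        g = rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        stat, p = mks.hwe_chisq(*(int((g == k).sum()) for k in range(3)))
        if not np.isnan(p):
            tested += 1
            rej += p < alpha
    rate = rej / tested
    se = np.sqrt(alpha * (1 - alpha) / tested)
    assert abs(rate - alpha) < 3.5 * se


def test_ld_r2_identical_and_relabelled():
    dos = np.array([[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 0, 2], [1, 1, 1]] * 5)
    gm = _gm_from_dosage(dos, MKS[:3])
    ld = mks.ld_r2(gm, MKS[:3], min_shared=5)
    assert ld.r2.loc["M0", "M1"] == pytest.approx(1.0)
    # allele relabelling (dosage flipped) leaves R^2 at 1
    assert ld.r2.loc["M0", "M2"] == pytest.approx(1.0)


def test_ld_null_expectation():
    """Mean R^2 between independent loci is ~ 1/n."""
    rng = np.random.default_rng(3)
    n, n_loci = 400, 40
    dos = rng.binomial(2, 0.5, size=(n, n_loci)).astype(float)
    markers = [MarkerDef(f"M{i}", "1", "A", "C") for i in range(n_loci)]
    gm = _gm_from_dosage(dos, markers)
    ld = mks.ld_r2(gm, markers)
    vals = ld.r2.to_numpy()[np.triu_indices(n_loci, 1)]
    # E[r^2] = 1/n for independent loci; SE of the mean over ~800 pairs
    assert abs(np.nanmean(vals) - 1 / n) < 3 * (2 / n) / np.sqrt(len(vals))


def test_ld_zero_variance_undefined():
    dos = np.array([[1, 0], [1, 1], [1, 2], [1, 0], [1, 1]] * 4)
    gm = _gm_from_dosage(dos, MKS[:2])
    ld = mks.ld_r2(gm, MKS[:2], min_shared=5)
    assert np.isnan(ld.r2.loc["M0", "M1"])


def test_fst_extremes_and_brute_force():
    assert mks.fst_nei(0.0, 1.0) == pytest.approx(1.0)
    assert mks.fst_nei(0.3, 0.3) == pytest.approx(0.0)
    rng = np.random.default_rng(1)
    for p1, p2 in rng.uniform(0.05, 0.95, size=(10, 2)):
        h1, h2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        assert mks.fst_nei(p1, p2) == pytest.approx((ht - (h1 + h2) / 2) / ht)


def test_fst_weir_cockerham_extremes():
    # fixed for alternate alleles -> theta = 1; identical freqs -> ~0
    assert mks.fst_weir_cockerham(0.0, 1.0, 500, 500) == pytest.approx(1.0, abs=1e-3)
    assert abs(mks.fst_weir_cockerham(0.4, 0.4, 500, 500)) < 0.01


def test_rank_and_select_line_subset():
    rng = np.random.default_rng(5)
    n = 40
    # loci 0-1 fixed for alternate alleles between lines; 2-3 identical freqs
    dosA = np.column_stack([np.zeros(n), np.full(n, 2),
                            rng.binomial(2, 0.5, n), rng.binomial(2, 0.3, n)])
    dosB = np.column_stack([np.full(n, 2), np.zeros(n),
                            rng.binomial(2, 0.5, n), rng.binomial(2, 0.3, n)])
    gm = _gm_from_dosage(np.vstack([dosA, dosB]), MKS,
                         lines=["LL"] * n + ["LC"] * n)
    sel = mks.rank_and_select(gm, MKS, fst_min=0.075, ld_max=1.01)
    assert set(sel.line_subset) == {"M0", "M1"}
    assert sel.locus_stats.loc["M0", "fst"] == pytest.approx(1.0)
    assert abs(sel.locus_stats.loc["M2", "fst"]) < 0.075


def test_private_alleles():
    n = 10
    # allele C present only in LL at M0
    dosA = np.column_stack([np.ones(n), np.ones(n)])
    dosB = np.column_stack([np.zeros(n), np.ones(n)])
    gm = _gm_from_dosage(np.vstack([dosA, dosB]), MKS[:2],
                         lines=["LL"] * n + ["LC"] * n)
    priv = mks.private_alleles(gm, MKS[:2])
    rec = priv[priv["marker_id"] == "M0"]
    assert len(rec) == 1 and rec.iloc[0]["allele"] == "C" and rec.iloc[0]["group"] == "LL"


def test_selection_idempotent(small_truth, panel):
    gm = small_truth.true_genotypes
    ind = pio.subset(panel, "individualisation")
    sel1 = mks.rank_and_select(gm, ind, ld_min_shared=10)
    by_id = {m.marker_id: m for m in ind}
    subset_defs = [by_id[m] for m in sel1.diversity_subset]
    sel2 = mks.rank_and_select(gm.restrict(subset_defs), subset_defs, ld_min_shared=10)
    assert sel2.diversity_subset == sel1.diversity_subset


def test_relative_filter_is_applied(small_truth, panel):
    """Removing first-degree relatives changes the frequency-estimation set
    (and hence can change FST ranking) on family-structured data."""
    ped = small_truth.pedigree
    # genotype only the sampled set: the living plus their recorded parents
    # (as in a monitoring study; a fully genotyped pedigree would collapse
    # to founders under the both-parents-genotyped rule)
    living = list(ped.table.index[ped.table["alive"]])
    parents = {p for i in living for p in ped.parents(i) if p is not None}
    sampled = sorted(set(living) | parents)
    full = small_truth.true_genotypes
    gm = pio.GenotypeMatrix(full.genotypes.loc[sampled], full.labels.loc[sampled])
    filtered = mks.remove_first_degree(gm, ped)
    assert len(filtered.individuals) < len(gm.individuals)
    present = set(gm.individuals)
    for iid in filtered.individuals:
        sire, dam = ped.parents(iid)
        assert not (sire in present and dam in present)
    ind = pio.subset(panel, "individualisation")
    sel_all = mks.rank_and_select(gm, ind, ld_min_shared=10)
    sel_flt = mks.rank_and_select(gm, ind, pedigree=ped, ld_min_shared=10)
    assert sel_flt.reference_individuals != sel_all.reference_individuals
    assert not sel_flt.locus_stats["fst"].equals(sel_all.locus_stats["fst"])


def test_group_too_small_errors():
    gm = _gm_from_dosage(np.zeros((3, 2)), MKS[:2], lines=["LL", "LC", "LC"])
    with pytest.raises(PanelError, match="fewer than 2"):
        mks.rank_and_select(gm, MKS[:2])
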