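import numpy as np
import pandas as pd
import pytest

from wisentpanel import diversity as div
from wisentpanel import panel_io as pio
from wisentpanel import simulate as sim
from wisentpanel.panel_io import NO_CALL, GenotypeMatrix, MarkerDef, PanelError, pedigree_from_records

MKS = [MarkerDef(f"M{i}", "1", "A", "C") for i in range(6)]


def gm_from_dosage(dos, markers=None, lines=None):
    markers = markers or MKS[: dos.shape[1]]
    rows = [[markers[j].genotypes[int(d)] if not np.isnan(d) else NO_CALL
             for j, d in enumerate(r)] for r in dos]
    genos = pd.DataFrame(rows, columns=[m.marker_id for m in markers],
                         index=[f"I{i}" for i in range(len(dos))])
    labels = pd.DataFrame({"group": "focal",
                           "line": lines if lines is not None else "U",
                           "sex": "U"}, index=genos.index)
    return GenotypeMatrix(genos, labels)


def test_heterozygote_excess_gives_negative_fis():
    n = 20
    dos = np.column_stack([np.ones(2 * n), np.ones(2 * n)])  # everyone A/C
    gm = gm_from_dosage(dos, MKS[:2], lines=["LL"] * n + ["LC"] * n)
    t = div.molecular_diversity(gm, MKS[:2]).table
    assert t.loc["total", "h_o"] == pytest.approx(1.0)
    assert t.loc["total", "fis_mode1"] < 0
    assert t.loc["total", "fis_mode2"] < 0


def test_fixed_opposite_groups_fst_one_both_modes():
    n = 15
    dos = np.vstack([np.zeros((n, 3)), np.full((n, 3), 2.0)])
    gm = gm_from_dosage(dos, MKS[:3], lines=["LL"] * n + ["LC"] * n)
    t = div.molecular_diversity(gm, MKS[:3]).table
    assert t.loc["total", "h_s"] == pytest.approx(0.0)
    assert t.loc["total", "h_t"] == pytest.approx(0.5)
    assert t.loc["total", "fst_mode1"] == pytest.approx(1.0)
    assert t.loc["total", "fst_mode2"] == pytest.approx(1.0)


def test_monomorphic_locus_ar_floor():
    n = 12
    dos = np.column_stack([np.zeros(2 * n), np.ones(2 * n)])
    gm = gm_from_dosage(dos, MKS[:2], lines=["LL"] * n + ["LC"] * n)
    res = div.molecular_diversity(gm, MKS[:2])
    # M0 monomorphic everywhere: its rarefied richness is exactly 1; with the
    # fully heterozygous M1 (richness 2) the per-group mean is 1.5
    assert res.table.loc["total", "ar"] == pytest.approx(1.5)
    assert res.notes.get("excluded_monomorphic", 0) == 1


def test_fstat_identity_in_mean_h_mode():
    rng = np.random.default_rng(0)
    n = 40
    dos = np.vstack([rng.binomial(2, 0.3, (n, 6)), rng.binomial(2, 0.7, (n, 6))]).astype(float)
    gm = gm_from_dosage(dos, MKS, lines=["LL"] * n + ["LC"] * n)
    t = div.molecular_diversity(gm, MKS).table
    lhs = 1 - t.loc["total", "fit_mode2"]
    rhs = (1 - t.loc["total", "fis_mode2"]) * (1 - t.loc["total", "fst_mode2"])
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_random_mating_fis_near_zero():
    rng = np.random.default_rng(1)
    n, n_loci = 150, 400
    markers = [MarkerDef(f"L{i}", "1", "A", "C") for i in range(n_loci)]
    qs = rng.uniform(0.2, 0.8, n_loci)
    dos = np.column_stack([rng.binomial(2, q, n) for q in qs]).astype(float)
    gm = gm_from_dosage(dos, markers, lines=["LL"] * (n // 2) + ["LC"] * (n - n // 2))
    t = div.molecular_diversity(gm, markers).table
    se = t.loc["total", "fis_se"]
    assert abs(t.loc["total", "fis_mode1"]) < 3 * se


def test_allele_relabelling_invariance():
    rng = np.random.default_rng(2)
    n = 30
    dos = rng.binomial(2, 0.3, (2 * n, 4)).astype(float)
    lines = ["LL"] * n + ["LC"] * n
    t1 = div.molecular_diversity(gm_from_dosage(dos, MKS[:4], lines=lines), MKS[:4]).table
    t2 = div.molecular_diversity(gm_from_dosage(2 - dos, MKS[:4], lines=lines), MKS[:4]).table
    for col in ("h_o", "uh_e", "ar", "fst_mode1", "fis_mode2"):
        assert t1.loc["total", col] == pytest.approx(t2.loc["total", col], abs=1e-12)


# ---------------------------------------------------------------------------
# pedigree engine


def _ped(records):
    return pedigree_from_records(records)


def test_kinship_textbook_values():
    # parent-offspring with unrelated parents: f = 0.25
    ped = _ped([
        {"id": "S", "sire": None, "dam": None, "sex": "M"},
        {"id": "D", "sire": None, "dam": None, "sex": "F"},
        {"id": "K", "sire": "S", "dam": "D", "sex": "M"},
    ])
    kin = div.pedigree_kinship(ped)
    assert kin.f.loc["S", "K"] == pytest.approx(0.25)
    assert kin.f.loc["S", "S"] == pytest.approx(0.5)
    assert kin.inbreeding["K"] == 0.0

    # full-sib mating: offspring F = 0.25
    ped2 = _ped([
        {"id": "S", "sire": None, "dam": None, "sex": "M"},
        {"id": "D", "sire": None, "dam": None, "sex": "F"},
        {"id": "B1", "sire": "S", "dam": "D", "sex": "M"},
        {"id": "B2", "sire": "S", "dam": "D", "sex": "F"},
        {"id": "X", "sire": "B1", "dam": "B2", "sex": "M"},
    ])
    kin2 = div.pedigree_kinship(ped2)
    assert kin2.inbreeding["X"] == pytest.approx(0.25)
    assert kin2.f.loc["X", "X"] == pytest.approx(0.625)
    assert kin2.f.loc["B1", "B2"] == pytest.approx(0.25)


def test_gene_diversity_two_founders():
    ped = _ped([
        {"id": "A", "sire": None, "dam": None, "sex": "M", "alive": True},
        {"id": "B", "sire": None, "dam": None, "sex": "F", "alive": True},
    ])
    gd = div.gene_diversity(ped, iterations=5, seed=0)
    # 4 equifrequent founder alleles: GD = 1 - 4 (1/4)^2 = 0.75, exactly,
    # under both estimators
    assert gd.gd_kinship == pytest.approx(0.75)
    assert gd.gd_genedrop == pytest.approx(0.75)
    assert gd.founder_contributions.sum() == pytest.approx(1.0)

    single = div.gene_diversity(ped, living=["A"], iterations=3, seed=0)
    assert single.gd_kinship == pytest.approx(0.5)


def test_gene_diversity_errors():
    ped = _ped([{"id": "A", "sire": None, "dam": None, "sex": "M", "alive": True}])
    with pytest.raises(PanelError, match="absent"):
        div.gene_diversity(ped, living=["ghost"], iterations=1)
    with pytest.raises(PanelError):
        div.gene_diversity(ped, living=["A"], iterations=0)


def test_genedrop_matches_kinship_closed_form():
    """Gene drop is an unbiased Monte-Carlo estimator of 1 - mean kinship."""
    rng = np.random.default_rng(3)
    recs = [{"id": f"F{i}", "sire": None, "dam": None,
             "sex": "M" if i % 2 == 0 else "F", "alive": False} for i in range(6)]
    ids = [r["id"] for r in recs]
    for g in range(25):
        males = [r["id"] for r in recs if r["sex"] == "M"]
        females = [r["id"] for r in recs if r["sex"] == "F"]
        iid = f"X{g}"
        recs.append({"id": iid, "sire": males[rng.integers(len(males))],
                     "dam": females[rng.integers(len(females))],
                     "sex": "M" if rng.random() < 0.5 else "F", "alive": g >= 15})
    ped = _ped(recs)
    gd = div.gene_diversity(ped, iterations=3000, seed=11)
    assert abs(gd.gd_genedrop - gd.gd_kinship) < 3.3 * gd.gd_genedrop_se


def test_pedigree_fstats_zero_and_sign():
    # two groups of mutually unrelated non-inbred individuals
    recs = [{"id": f"A{i}", "sire": None, "dam": None, "sex": "M", "line": "LL",
             "alive": True} for i in range(4)]
    recs += [{"id": f"B{i}", "sire": None, "dam": None, "sex": "F", "line": "LC",
              "alive": True} for i in range(4)]
    fs = div.pedigree_f_stats(_ped(recs))
    assert fs["f_is"] == pytest.approx(0.0)
    assert fs["f_st"] == pytest.approx(0.0)
    assert fs["f_it"] == pytest.approx(0.0)

    # two separate sib-groups: within-line coancestry > 0, between = 0
    recs2 = []
    for line, tag in (("LL", "A"), ("LC", "B")):
        recs2 += [
            {"id": f"{tag}S", "sire": None, "dam": None, "sex": "M", "line": line},
            {"id": f"{tag}D", "sire": None, "dam": None, "sex": "F", "line": line},
        ]
        recs2 += [{"id": f"{tag}K{i}", "sire": f"{tag}S", "dam": f"{tag}D",
                   "sex": "M", "line": line, "alive": True} for i in range(3)]
    fs2 = div.pedigree_f_stats(_ped(recs2))
    assert fs2["f_st"] > 0
    # identity between the three statistics holds by construction
    assert (1 - fs2["f_it"]) == pytest.approx((1 - fs2["f_is"]) * (1 - fs2["f_st"]))

    with pytest.raises(PanelError, match="groups"):
        div.pedigree_f_stats(_ped(recs[:4]))


def test_molecular_and_pedigree_table_side_by_side(small_truth, panel):
    gm = small_truth.true_genotypes
    pdm = pio.subset(panel, "parentage_diversity")
    keep = gm.labels.index[gm.labels["line"].isin(["LL", "LC"])]
    gm2 = GenotypeMatrix(gm.genotypes.loc[keep], gm.labels.loc[keep])
    table = div.diversity_table(gm2, pdm, small_truth.pedigree, living=set(keep),
                                iterations=100, seed=0)
    for col in ("gd_kinship", "gd_genedrop", "fst_pedigree", "fst_mode1"):
        assert np.isfinite(table.table.loc["total", col])
    assert 0 < table.table.loc["total", "gd_kinship"] < 1
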