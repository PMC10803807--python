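import itertools

import numpy as np
import pandas as pd
import pytest

from wisentpanel import identity as idn
from wisentpanel import panel_io as pio
from wisentpanel import simulate as sim
from wisentpanel.panel_io import NO_CALL, GenotypeMatrix, MarkerDef, PanelError


def freq_frame(qs):
    return pd.DataFrame(
        {"freq_a": [1 - q for q in qs], "freq_b": qs,
         "n_copies": [100] * len(qs),
         "h_e": [2 * q * (1 - q) for q in qs]},
        index=[f"L{i}" for i in range(len(qs))],
    )


def test_pid_closed_form_half():
    assert idn.pid_single_locus([0.5, 0.5]) == pytest.approx(0.375)
    assert idn.pidsib_single_locus([0.5, 0.5]) == pytest.approx(0.59375)


def test_pid_monomorphic_is_one():
    assert idn.pid_single_locus([1.0, 0.0]) == pytest.approx(1.0)
    assert idn.pidsib_single_locus([1.0, 0.0]) == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="monomorphic|polymorphic"):
        curve = idn.pid_curves(freq_frame([0.0, 1.0]))
    assert (curve.table["cum_pid"] == 1.0).all()


def test_pidsib_dominates_pid_on_grid():
    """PIDsib >= PID at every allele frequency (brute-force over a grid)."""
    for q in np.linspace(0.0, 1.0, 41):
        assert idn.pidsib_single_locus([1 - q, q]) >= idn.pid_single_locus([1 - q, q]) - 1e-15


def test_pid_curves_non_increasing_and_threshold():
    qs = [0.5] * 30
    curve = idn.pid_curves(freq_frame(qs), threshold=1e-4)
    t = curve.table
    assert (np.diff(t["log10_cum_pid"]) <= 1e-12).all()
    assert (np.diff(t["log10_cum_pidsib"]) <= 1e-12).all()
    # 0.375^k <= 1e-4 first at k = 10; 0.59375^k <= 1e-4 first at k = 18
    assert curve.loci_to_pid == 10
    assert curve.loci_to_pidsib == 18


def _gm(rows, markers, sexes=None):
    genos = pd.DataFrame(rows, columns=[m.marker_id for m in markers]).astype(str)
    genos.index = [f"I{i}" for i in range(len(rows))]
    labels = pd.DataFrame({"group": "focal", "line": "U",
                           "sex": sexes or ["U"] * len(rows)}, index=genos.index)
    return GenotypeMatrix(genos, labels)


MKS = [MarkerDef(f"M{i}", "1", "A", "C") for i in range(3)]


def test_mismatch_counting():
    gm = _gm([["A/A", "A/C", "C/C"], ["A/A", "C/C", "C/C"]], MKS)
    mm = idn.match_individuals(gm, MKS, max_mismatch=0)
    assert mm.mismatches.loc["I0", "I1"] == 1
    assert mm.compared.loc["I0", "I1"] == 3
    assert mm.mismatches.equals(mm.mismatches.T)
    assert (np.diag(mm.mismatches) == 0).all()


def test_mismatch_ignores_disjoint_missingness():
    gm = _gm([["A/A", NO_CALL, "C/C"], ["A/A", "A/C", NO_CALL]], MKS)
    mm = idn.match_individuals(gm, MKS, max_mismatch=3)
    assert mm.mismatches.loc["I0", "I1"] == 0
    assert mm.compared.loc["I0", "I1"] == 1
    assert mm.groups == [["I0", "I1"]]


def test_incomparable_pair_flagged():
    gm = _gm([["A/A", NO_CALL, NO_CALL], [NO_CALL, "A/C", "C/C"]], MKS)
    mm = idn.match_individuals(gm, MKS)
    assert ("I0", "I1") in mm.incomparable


def test_duplicate_samples_recovered_at_panel_error_rates(panel):
    """Two noisy observations of the same individual stay well below the
    between-individual mismatch floor and are grouped together."""
    truth = sim.simulate_population(sim.SimConfig(seed=21, n_generations=3,
                                                  offspring_per_pair=2.5))
    ids = list(truth.pedigree.table.index)[:30]
    cfg = truth.config
    rcs1, _ = sim.observe_replicates(truth, cfg, individuals=ids)
    from wisentpanel import consensus as cns

    gm1, _ = cns.consensus_matrix(rcs1, panel)
    dup = gm1.genotypes.loc[[ids[0]]].rename(index={ids[0]: "dup_0"})
    merged = GenotypeMatrix(
        pd.concat([gm1.genotypes, dup]),
        pd.concat([gm1.labels, gm1.labels.loc[[ids[0]]].rename(index={ids[0]: "dup_0"})]),
    )
    ind = pio.subset(panel, "individualisation")
    mm = idn.match_individuals(merged, ind, max_mismatch=3)
    assert {"dup_0", ids[0]} in [set(g) for g in mm.groups]
    off_diag = mm.mismatches.loc[ids, ids].to_numpy()[np.triu_indices(len(ids), 1)]
    assert off_diag.min() > 3


# ---------------------------------------------------------------------------
# parentage


def test_transition_matrix_rows_sum_to_one():
    for q in np.linspace(0.01, 0.99, 21):
        t = idn.transition_matrix(q)
        assert np.allclose(t.sum(axis=1), 1.0)
        assert np.allclose(idn.hwe_probs(q).sum(), 1.0)


def test_transition_matrix_brute_force():
    """T equals enumeration over transmitted alleles with an HWE co-parent."""
    rng = np.random.default_rng(0)
    for q in rng.uniform(0.05, 0.95, 5):
        p = 1 - q
        for gc in range(3):
            probs = np.zeros(3)
            trans = {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}[gc]
            for allele_c, w in trans:
                for allele_o, wo in ((0, p), (1, q)):
                    probs[allele_c + allele_o] += w * wo
            assert np.allclose(idn.transition_matrix(q)[gc], probs)


def test_opposing_homozygotes_counted_and_lod_example():
    m = MarkerDef("M0", "1", "A", "C")
    gm = _gm([["A/A"], ["C/C"], ["A/C"]], [m], sexes=["U", "M", "F"])
    freqs = freq_frame([0.5]).rename(index={"L0": "M0"})
    po = idn.assign_parents(gm, freqs, [m], epsilon=0.0)
    t = po.table.set_index(["focal", "candidate"])
    assert t.loc[("I0", "I1"), "exclusions"] == 1
    # offspring AB vs candidate AA at q=0.5: T = 0.5 = P_HW(AB) -> LOD 0
    assert t.loc[("I2", "I0"), "lod"] == pytest.approx(0.0)


def test_epsilon_zero_reduces_to_pure_exclusion():
    m = [MarkerDef(f"M{i}", "1", "A", "C") for i in range(2)]
    gm = _gm([["A/A", "A/A"], ["C/C", "A/A"]], m)
    freqs = pd.DataFrame({"freq_a": [0.5, 0.5], "freq_b": [0.5, 0.5],
                          "n_copies": [40, 40], "h_e": [0.5, 0.5]},
                         index=["M0", "M1"])
    po = idn.assign_parents(gm, freqs, m, epsilon=0.0, max_exclusions=0)
    t = po.table.set_index(["focal", "candidate"])
    assert t.loc[("I0", "I1"), "lod"] == -np.inf
    assert t.loc[("I0", "I1"), "decision"] == "rejected"


def test_epsilon_bounds():
    m = [MarkerDef("M0", "1", "A", "C")]
    gm = _gm([["A/A"], ["A/A"]], m)
    freqs = freq_frame([0.5]).rename(index={"L0": "M0"})
    with pytest.raises(PanelError):
        idn.assign_parents(gm, freqs, m, epsilon=0.7)


def test_trio_network_categories(panel):
    # informative (het-enriched) loci and a broad founder base keep true-pair
    # LODs positive, so network categories are exercised deterministically
    truth = sim.simulate_population(sim.SimConfig(seed=4, n_generations=2,
                                                  n_founders_total=20,
                                                  n_founders_lineA=10,
                                                  founder_freq_prior=(8, 8),
                                                  offspring_per_pair=2.5))
    gm = truth.true_genotypes
    pdm = pio.subset(panel, "parentage_diversity")
    freqs = idn.allele_frequencies(gm, pdm)
    po = idn.assign_parents(gm, freqs, pdm)
    net = idn.build_family_network(po, truth.pedigree)
    assert net.counts["not_testable"] == 0
    # error-free genotypes: every studbook PO link is genetically verified
    assert net.counts["not_verified"] == 0
    assert net.counts["verified"] == len(truth.pedigree.po_pairs())

    # withholding the dam's genotype makes her links not-testable
    dam = truth.pedigree.table["dam"].dropna().iloc[0]
    keep = [i for i in gm.individuals if i != dam]
    gm2 = GenotypeMatrix(gm.genotypes.loc[keep], gm.labels.loc[keep])
    po2 = idn.assign_parents(gm2, idn.allele_frequencies(gm2, pdm), pdm)
    net2 = idn.build_family_network(po2, truth.pedigree, genotyped=set(keep))
    n_dam_links = sum(1 for pair in truth.pedigree.po_pairs() if dam in pair)
    assert net2.counts["not_testable"] == n_dam_links
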