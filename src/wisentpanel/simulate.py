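"""Synthetic two-breeding-line pedigree populations with a non-invasive
replicate observation model.

The generator emulates the structure of the managed European bison
population: a 12-founder bottleneck, a split into a lowland line (founded by
a nested subset of 7 founders) and a lowland–Caucasian line (founded by all
12), one-directional gene flow from the lowland line into the other, unlinked
biallelic autosomal markers dropped through the pedigree under Mendelian
inheritance, and a Y-associated sex marker. Observed replicate calls are the
truth corrupted by independent per-call allelic dropout (ADO), false-allele
(FA) and missingness events; every injected event is retained in an event log
so estimators can be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel_io import (
    NO_CALL,
    GenotypeMatrix,
    MarkerDef,
    PanelError,
    Pedigree,
    ReplicateCalls,
    default_panel,
    pedigree_from_records,
)

#: default per-call missingness solved so the expected call rate matches the
#: 92.4% (non-invasive) and 98% (invasive) marginals; ADO/FA never produce
#: missing calls in this model, so p_miss = 1 - call rate.
DEFAULT_P_MISS = {"noninvasive": 1 - 0.924, "invasive": 1 - 0.98}


@dataclass(frozen=True)
class ErrorProfile:
    """Per replicate-call error probabilities; events are independent."""

    p_ado: float = 0.016
    p_fa: float = 0.003
    p_miss: dict = field(default_factory=lambda: dict(DEFAULT_P_MISS))

    def __post_init__(self):
        for name, p in (("p_ado", self.p_ado), ("p_fa", self.p_fa)):
            if not 0 <= p <= 1:
                raise PanelError(f"{name} must be in [0,1], got {p}")
        for k, p in self.p_miss.items():
            if not 0 <= p <= 1:
                raise PanelError(f"p_miss[{k}] must be in [0,1], got {p}")


@dataclass
class SimConfig:
    """Configuration of the synthetic population and observation model."""

    n_founders_total: int = 12
    n_founders_lineA: int = 7  # nested founder subset for the lowland line
    n_generations: int = 6
    offspring_per_pair: float = 3.2  # Poisson mean per mated pair
    polygamy: bool = True
    migration: float = 0.10  # per-offspring prob of a lineA sire in lineB
    markers: list | None = None  # default: the shipped 96-marker panel
    founder_freq_prior: tuple = (2.0, 2.0)  # Beta(alpha, beta)
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    replicate_plan: dict = field(default_factory=lambda: {"noninvasive": 3, "invasive": 1})
    invasive_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.markers is None:
            self.markers = default_panel()
        if not 0 <= self.migration <= 1:
            raise PanelError("migration must be a probability")
        if self.n_founders_lineA > self.n_founders_total:
            raise PanelError("n_founders_lineA must be nested in n_founders_total")


@dataclass
class TruthSet:
    """Ground truth of one simulation run."""

    pedigree: Pedigree
    true_genotypes: GenotypeMatrix
    founder_freqs: pd.Series  # frequency of allele_b per autosomal marker
    config: SimConfig

    @property
    def lines(self) -> pd.Series:
        return self.pedigree.table["line"]


def _marker_arrays(markers):
    auto = [m for m in markers if m.is_autosomal]
    sex = [m for m in markers if not m.is_autosomal]
    return auto, sex


def _genotype_strings(markers, dosage_row):
    return [m.genotypes[int(d)] for m, d in zip(markers, dosage_row)]


def simulate_population(cfg: SimConfig) -> TruthSet:
    """Simulate pedigree + true genotypes; deterministic under ``cfg.seed``.

    Founders (generation 0) are the shared pre-split stock (line label ``U``).
    Generation 1 of line ``LL`` descends from the nested founder subset,
    generation 1 of ``LC`` from all founders; from then on each line breeds
    within itself except for one-directional ``LL -> LC`` sire migration.
    """
    if cfg.n_founders_total < 2:
        raise PanelError("need at least 2 founders")
    auto_markers, sex_markers = _marker_arrays(cfg.markers)
    if not auto_markers:
        raise PanelError("need at least 1 autosomal marker")
    rng = np.random.default_rng(cfg.seed)
    n_loci = len(auto_markers)

    # founder allele-b frequencies; cross-species markers are monomorphic in
    # the focal species by construction (frequency of allele_b = 0)
    alpha, beta = cfg.founder_freq_prior
    freqs = rng.beta(alpha, beta, size=n_loci)
    for i, m in enumerate(auto_markers):
        if "cross_species" in m.subsets:
            freqs[i] = 0.0
    founder_freqs = pd.Series(freqs, index=[m.marker_id for m in auto_markers])

    records, dosages, sexes = [], {}, {}

    def add_individual(iid, sire, dam, sex, line, gen):
        records.append(
            {"id": iid, "sire": sire, "dam": dam, "sex": sex, "line": line,
             "alive": gen == cfg.n_generations}
        )
        sexes[iid] = sex

    founders = []
    for k in range(cfg.n_founders_total):
        iid = f"F{k + 1:03d}"
        sex = "M" if k % 2 == 0 else "F"
        add_individual(iid, None, None, sex, "U", 0)
        dosages[iid] = (rng.random((2, n_loci)) < freqs).sum(axis=0).astype(np.int8)
        founders.append(iid)

    pools = {"LL": founders[: cfg.n_founders_lineA], "LC": list(founders)}

    def breed(pool, line, gen):
        males = [i for i in pool if sexes[i] == "M"]
        females = [i for i in pool if sexes[i] == "F"]
        if not males or not females:
            return []
        children = []
        n_pairs = len(females)
        for j in range(n_pairs):
            dam = females[j]
            sire = males[int(rng.integers(len(males)))] if cfg.polygamy else males[j % len(males)]
            if line == "LC" and cfg.migration > 0 and pools["LL"]:
                ll_males = [i for i in pools["LL"] if sexes[i] == "M"]
                if ll_males and rng.random() < cfg.migration:
                    sire = ll_males[int(rng.integers(len(ll_males)))]
            n_off = int(rng.poisson(cfg.offspring_per_pair))
            if j == n_pairs - 1 and not children and n_off == 0:
                n_off = 2  # keep the line alive through a bad draw
            for c in range(n_off):
                iid = f"G{gen}_{line}_{len(children) + 1:04d}"
                sex = "M" if rng.random() < 0.5 else "F"
                add_individual(iid, sire, dam, sex, line, gen)
                ds, dd = dosages[sire], dosages[dam]
                child = (rng.random(n_loci) < ds / 2.0).astype(np.int8) + (
                    rng.random(n_loci) < dd / 2.0
                ).astype(np.int8)
                dosages[iid] = child
                children.append(iid)
        # keep both sexes present so the line can continue breeding
        if children and gen < cfg.n_generations:
            kid_sexes = {sexes[c] for c in children}
            if len(kid_sexes) == 1:
                flip = children[0]
                sexes[flip] = "M" if sexes[flip] == "F" else "F"
                for rec in records:
                    if rec["id"] == flip:
                        rec["sex"] = sexes[flip]
        return children

    for gen in range(1, cfg.n_generations + 1):
        new_pools = {}
        for line in ("LL", "LC"):
            new_pools[line] = breed(pools[line], line, gen)
        for line in ("LL", "LC"):
            if new_pools[line]:
                pools[line] = new_pools[line]

    ped = pedigree_from_records(records)
    ids = list(ped.table.index)
    geno_rows = {}
    for iid in ids:
        row = _genotype_strings(auto_markers, dosages[iid])
        for m in sex_markers:
            row.append("XY" if sexes[iid] == "M" else "X")
        geno_rows[iid] = row
    columns = [m.marker_id for m in auto_markers] + [m.marker_id for m in sex_markers]
    genos = pd.DataFrame.from_dict(geno_rows, orient="index", columns=columns)
    labels = pd.DataFrame(
        {
            "group": "focal",
            "line": ped.table["line"],
            "sex": ped.table["sex"],
        },
        index=genos.index,
    )
    gm = GenotypeMatrix(genos, labels)
    return TruthSet(ped, gm, founder_freqs, cfg)


def observe_replicates(truth: TruthSet, cfg: SimConfig | None = None,
                       individuals: list | None = None):
    """Generate replicate-level noisy observations of the true genotypes.

    Per call, independently: NoCall with ``p_miss``; else a heterozygote loses
    one allele with ``p_ado`` (false homozygote), a homozygote gains the
    marker's other allele with ``p_fa`` (false heterozygote). The sex marker
    uses the same mechanisms: a spurious Y in females is an FA event, a
    dropped Y in males an ADO event.

    Returns ``(replicate_calls, event_log)`` where the event log is a
    DataFrame of every injected error (sample, replicate, marker, event,
    true and observed call).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    prof = cfg.error_profile
    gm = truth.true_genotypes
    by_id = {m.marker_id: m for m in cfg.markers}
    mids = list(gm.genotypes.columns)
    if individuals is None:
        individuals = list(gm.genotypes.index)

    rcs, events = [], []
    for iid in individuals:
        stype = "invasive" if rng.random() < cfg.invasive_fraction else "noninvasive"
        r = cfg.replicate_plan[stype]
        p_miss = prof.p_miss.get(stype, 0.0)
        true_row = gm.genotypes.loc[iid]
        rep_rows = {}
        for rep in range(1, r + 1):
            rep_id = f"rep{rep}"
            u = rng.random((3, len(mids)))
            obs = []
            for j, mid in enumerate(mids):
                g = true_row[mid]
                m = by_id[mid]
                if u[0, j] < p_miss:
                    obs.append(NO_CALL)
                    events.append((f"S_{iid}", rep_id, mid, "miss", g, NO_CALL))
                    continue
                if m.is_autosomal:
                    a, b = sorted(m.alleles)
                    het = f"{a}/{b}"
                    if g == het:
                        if u[1, j] < prof.p_ado:
                            kept = a if u[2, j] < 0.5 else b
                            o = f"{kept}/{kept}"
                            obs.append(o)
                            events.append((f"S_{iid}", rep_id, mid, "ado", g, o))
                            continue
                    else:
                        if u[1, j] < prof.p_fa:
                            obs.append(het)
                            events.append((f"S_{iid}", rep_id, mid, "fa", g, het))
                            continue
                else:  # sex marker: X / XY
                    if g == "X" and u[1, j] < prof.p_fa:
                        obs.append("XY")
                        events.append((f"S_{iid}", rep_id, mid, "fa", g, "XY"))
                        continue
                    if g == "XY" and u[1, j] < prof.p_ado:
                        obs.append("X")
                        events.append((f"S_{iid}", rep_id, mid, "ado", g, "X"))
                        continue
                obs.append(g)
            rep_rows[rep_id] = obs
        calls = pd.DataFrame.from_dict(rep_rows, orient="index", columns=mids)
        rcs.append(ReplicateCalls(f"S_{iid}", calls, individual_id=iid, sample_type=stype))
    log = pd.DataFrame(
        events,
        columns=["sample_id", "replicate_id", "marker_id", "event", "true", "observed"],
    )
    return rcs, log


@dataclass(frozen=True)
class EsuSpec:
    """One non-target evolutionarily significant unit for cross-species tests."""

    name: str
    n_individuals: int = 8
    call_rate: float = 0.9
    freq_shift: float = 0.3  # magnitude of per-marker allele-frequency offset
    cross_species_polymorphic: bool = False

    def __post_init__(self):
        if self.call_rate < 0:
            raise PanelError(f"{self.name}: negative call rate")


def make_nontarget_genotypes(cfg: SimConfig, divergence: list,
                             founder_freqs: pd.Series | None = None) -> GenotypeMatrix:
    """Genotypes for non-target ESUs with shifted frequencies and phylogenetic
    dropout (per-ESU baseline call rates).

    Cross-species-flagged markers are monomorphic in the focal species but
    polymorphic (frequency 0.5) in ESUs flagged ``cross_species_polymorphic``.
    """
    rng = np.random.default_rng(cfg.seed + 7_000_017)
    auto_markers, _ = _marker_arrays(cfg.markers)
    n_loci = len(auto_markers)
    if founder_freqs is None:
        alpha, beta = cfg.founder_freq_prior
        base = rng.beta(alpha, beta, size=n_loci)
        for i, m in enumerate(auto_markers):
            if "cross_species" in m.subsets:
                base[i] = 0.0
    else:
        base = founder_freqs.reindex([m.marker_id for m in auto_markers]).to_numpy()

    rows, labels = {}, []
    for esu in divergence:
        signs = rng.choice([-1.0, 1.0], size=n_loci)
        freqs = np.clip(base + signs * esu.freq_shift, 0.0, 1.0)
        for i, m in enumerate(auto_markers):
            if "cross_species" in m.subsets:
                freqs[i] = 0.5 if esu.cross_species_polymorphic else 0.0
        for k in range(esu.n_individuals):
            iid = f"{esu.name}_{k + 1:02d}"
            dos = (rng.random((2, n_loci)) < freqs).sum(axis=0)
            row = _genotype_strings(auto_markers, dos)
            miss = rng.random(n_loci) > esu.call_rate
            row = [NO_CALL if miss[i] else g for i, g in enumerate(row)]
            rows[iid] = row
            labels.append({"group": esu.name, "line": "U", "sex": "U"})
    genos = pd.DataFrame.from_dict(
        rows, orient="index", columns=[m.marker_id for m in auto_markers]
    )
    label_df = pd.DataFrame(labels, index=genos.index)
    return GenotypeMatrix(genos, label_df)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of ``cfg`` with a different seed (convenience for seed sweeps)."""
    return replace(cfg, seed=int(seed))
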