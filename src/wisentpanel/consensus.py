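"""Consensus genotypes from replicated calls, genotyping-error decomposition
and Y-marker sex determination.

The consensus rules are deterministic and applied in a fixed precedence order
(most specific, heterozygote-forcing rules first). With per-marker replicate
tallies (n_AA, n_AB, n_BB) over called replicates:

1. all replicates missing                         -> NoCall
2. n_AB >= 1 and n_AA >= 2 and n_BB >= 2          -> AB (both opposite
   homozygotes seen at least twice alongside a heterozygote)
3. all three genotype classes present             -> AB
4. n_AB > 0 and n_AB >= max(n_AA, n_BB)           -> AB (hom/het ties go
   heterozygous)
5. unique plurality class                         -> that genotype
6. only the two homozygotes, tied                 -> NoCall

Genotyping-error events are scored per replicate call against the consensus:
an allelic dropout (ADO) is a homozygous replicate at a heterozygous
consensus; a false allele (FA) is a replicate carrying an allele absent from
the consensus. With biallelic markers the two are mutually exclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import (
    NO_CALL,
    GenotypeMatrix,
    MarkerDef,
    PanelError,
    ReplicateCalls,
)

#: default minimum replicate counts per sample type
DEFAULT_MIN_REPLICATES = {"noninvasive": 3, "invasive": 1}
#: loci whose GE rate exceeds this are flagged for exclusion
DEFAULT_GE_EXCLUDE = 0.05


@dataclass
class ConsensusResult:
    sample_id: str
    genotype: pd.Series  # per marker consensus call
    tallies: pd.DataFrame  # per marker: n_hom_a, n_het, n_hom_b, n_miss
    call_rate: float
    individual_id: str | None = None
    flagged: bool = False  # replicate count below the configured minimum
    sex: str = "undetermined"
    y_fraction: float | None = None


@dataclass
class SexCall:
    sex: str  # male / female / undetermined
    y_fraction: float | None
    reason: str = ""


@dataclass
class ErrorReport:
    per_locus: pd.DataFrame  # ado/fa/ge events, comparisons, rates, flagged
    per_sample: pd.DataFrame
    ge_exclude: float

    @property
    def mean_rates(self) -> dict:
        pl = self.per_locus
        tot = pl["comparisons"].sum()
        if tot == 0:
            return {"ado": float("nan"), "fa": float("nan"), "ge": float("nan")}
        return {
            "ado": pl["ado_events"].sum() / tot,
            "fa": pl["fa_events"].sum() / tot,
            "ge": (pl["ado_events"].sum() + pl["fa_events"].sum()) / tot,
        }

    @property
    def conditional_rates(self) -> dict:
        """Per-event-opportunity rates: ADO among heterozygous-consensus
        comparisons, FA among homozygous-consensus comparisons (the scale on
        which the per-replicate event probabilities are defined)."""
        pl = self.per_locus
        het = pl["het_comparisons"].sum()
        hom = pl["comparisons"].sum() - het
        ado = pl["ado_events"].sum() / het if het else float("nan")
        fa = pl["fa_events"].sum() / hom if hom else float("nan")
        return {"ado": ado, "fa": fa, "ge": ado + fa,
                "het_comparisons": int(het), "hom_comparisons": int(hom)}

    @property
    def flagged_loci(self) -> list:
        return list(self.per_locus.index[self.per_locus["flagged"]])


def consensus_call(calls, marker: MarkerDef) -> str:
    """Consensus of one marker's replicate calls by the precedence rules."""
    called = [c for c in calls if c != NO_CALL]
    if not called:
        return NO_CALL
    hom_a, het, hom_b = marker.genotypes
    n = Counter(called)
    n_a, n_h, n_b = n.get(hom_a, 0), n.get(het, 0), n.get(hom_b, 0)
    if n_h >= 1 and n_a >= 2 and n_b >= 2:
        return het
    if n_a >= 1 and n_h >= 1 and n_b >= 1:
        return het
    if n_h > 0 and n_h >= max(n_a, n_b):
        return het
    counts = {hom_a: n_a, het: n_h, hom_b: n_b}
    top = max(counts.values())
    winners = [g for g, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0]
    return NO_CALL  # opposite homozygotes scored 50:50


def determine_sex(rc: ReplicateCalls, sex_marker: MarkerDef) -> SexCall:
    """Majority vote over Y-bearing replicate calls at the gonosomal marker."""
    if sex_marker.marker_id not in rc.calls.columns:
        return SexCall("undetermined", None, "sex marker absent")
    col = rc.calls[sex_marker.marker_id]
    called = col[col != NO_CALL]
    if called.empty:
        return SexCall("undetermined", None, "no data")
    y_frac = float((called == "XY").mean())
    if y_frac > 0.5:
        return SexCall("male", y_frac)
    if y_frac < 0.5:
        return SexCall("female", y_frac)
    return SexCall("undetermined", y_frac, "tied replicates")


def build_consensus(rc: ReplicateCalls, markers: list,
                    min_replicates: dict | int | None = None) -> ConsensusResult:
    """Consensus multilocus genotype for one sample.

    Samples with fewer replicates than the per-sample-type minimum are
    flagged and their consensus withheld (all NoCall).
    """
    if min_replicates is None:
        min_replicates = DEFAULT_MIN_REPLICATES
    if isinstance(min_replicates, int):
        need = min_replicates
    else:
        need = min_replicates.get(rc.sample_type, 1)
    by_id = {m.marker_id: m for m in markers}
    mids = [c for c in rc.calls.columns if c in by_id]

    genos, tallies = {}, {}
    sex_call = SexCall("undetermined", None, "sex marker absent")
    flagged = rc.r < need
    for mid in mids:
        m = by_id[mid]
        col = list(rc.calls[mid])
        n_miss = sum(c == NO_CALL for c in col)
        if not m.is_autosomal:
            sex_call = determine_sex(rc, m)
            g = {"male": "XY", "female": "X"}.get(sex_call.sex, NO_CALL)
            n_y = sum(c == "XY" for c in col)
            tallies[mid] = {"n_hom_a": rc.r - n_miss - n_y, "n_het": n_y, "n_hom_b": 0,
                            "n_miss": n_miss}
        else:
            hom_a, het, hom_b = m.genotypes
            cnt = Counter(c for c in col if c != NO_CALL)
            tallies[mid] = {"n_hom_a": cnt.get(hom_a, 0), "n_het": cnt.get(het, 0),
                            "n_hom_b": cnt.get(hom_b, 0), "n_miss": n_miss}
            g = consensus_call(col, m)
        genos[mid] = NO_CALL if flagged else g
    genotype = pd.Series(genos)
    call_rate = float((genotype != NO_CALL).mean()) if len(genotype) else 0.0
    tally_df = pd.DataFrame.from_dict(tallies, orient="index")
    return ConsensusResult(
        rc.sample_id, genotype, tally_df, call_rate,
        individual_id=rc.individual_id, flagged=flagged,
        sex=sex_call.sex if not flagged else "undetermined",
        y_fraction=sex_call.y_fraction,
    )


def classify_event(consensus_g: str, replicate_g: str, marker: MarkerDef) -> str | None:
    """ADO / FA / None for one replicate call against its consensus."""
    if NO_CALL in (consensus_g, replicate_g) or consensus_g == replicate_g:
        return None
    if not marker.is_autosomal:
        # consensus XY (male): missing Y is a dropout; consensus X: gained Y is FA
        return "ado" if consensus_g == "XY" else "fa"
    hom_a, het, hom_b = marker.genotypes
    if consensus_g == het and replicate_g in (hom_a, hom_b):
        return "ado"
    cons_alleles = set(consensus_g.split("/"))
    rep_alleles = set(replicate_g.split("/"))
    if rep_alleles - cons_alleles:
        return "fa"
    return None


def estimate_error_rates(rcs: list, consensuses: list, markers: list,
                         ge_exclude: float = DEFAULT_GE_EXCLUDE) -> ErrorReport:
    """Score every replicate call against its sample's consensus.

    Rates are events / comparisons, aggregated per locus (across samples) and
    per sample (across loci); comparisons count replicate calls where both
    the replicate and the consensus are non-missing. Loci whose GE rate
    exceeds ``ge_exclude`` are flagged.
    """
    by_id = {m.marker_id: m for m in markers}
    cons_by_sample = {c.sample_id: c for c in consensuses}
    locus_counts = {mid: np.zeros(4, dtype=int) for mid in by_id}  # ado, fa, comp, het_comp
    sample_counts = {}
    for rc in rcs:
        cons = cons_by_sample.get(rc.sample_id)
        if cons is None or cons.flagged:
            continue
        counts = np.zeros(4, dtype=int)
        for mid in rc.calls.columns:
            if mid not in by_id:
                continue
            m = by_id[mid]
            cg = cons.genotype.get(mid, NO_CALL)
            if cg == NO_CALL:
                continue
            het = (m.is_autosomal and cg == m.genotypes[1]) or cg == "XY"
            for rep_g in rc.calls[mid]:
                if rep_g == NO_CALL:
                    continue
                ev = classify_event(cg, rep_g, m)
                locus_counts[mid][2] += 1
                counts[2] += 1
                if het:
                    locus_counts[mid][3] += 1
                    counts[3] += 1
                if ev == "ado":
                    locus_counts[mid][0] += 1
                    counts[0] += 1
                elif ev == "fa":
                    locus_counts[mid][1] += 1
                    counts[1] += 1
        sample_counts[rc.sample_id] = counts

    def to_frame(counts: dict) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            counts, orient="index",
            columns=["ado_events", "fa_events", "comparisons", "het_comparisons"],
        )
        comp = df["comparisons"].where(df["comparisons"] > 0)
        df["ado_rate"] = df["ado_events"] / comp
        df["fa_rate"] = df["fa_events"] / comp
        df["ge_rate"] = (df["ado_events"] + df["fa_events"]) / comp
        return df

    per_locus = to_frame(locus_counts)
    per_locus["flagged"] = per_locus["ge_rate"].fillna(0.0) > ge_exclude
    per_sample = to_frame(sample_counts)
    return ErrorReport(per_locus, per_sample, ge_exclude)


def consensus_matrix(rcs: list, markers: list,
                     min_replicates: dict | int | None = None) -> tuple:
    """Consensus genotypes for many samples as a GenotypeMatrix.

    Rows are keyed by individual id where known, else by sample id; sex labels
    come from the Y-marker caller. Returns ``(GenotypeMatrix, [ConsensusResult])``.
    Flagged samples (too few replicates) are excluded from the matrix.
    """
    results = [build_consensus(rc, markers, min_replicates) for rc in rcs]
    rows, labels, prov = {}, [], []
    for res in results:
        if res.flagged:
            continue
        key = res.individual_id or res.sample_id
        if key in rows:
            raise PanelError(f"duplicate individual id in consensus set: {key}")
        rows[key] = res.genotype
        labels.append({"group": "focal", "line": "U",
                       "sex": {"male": "M", "female": "F"}.get(res.sex, "U")})
        prov.append({"sample_id": res.sample_id, "call_rate": res.call_rate,
                     "replicates": int(res.tallies.iloc[0].sum()) if len(res.tallies) else 0})
    genos = pd.DataFrame.from_dict(rows, orient="index")
    gm = GenotypeMatrix(
        genos,
        pd.DataFrame(labels, index=genos.index),
        pd.DataFrame(prov, index=genos.index),
    )
    return gm, results
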