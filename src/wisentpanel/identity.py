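"""Individual discrimination and parent-offspring assignment.

Discrimination uses the probability of identity for unrelated individuals
(PID) and for full siblings (PIDsib), accumulated over loci sorted by
descending expected heterozygosity, plus pairwise allele-mismatch matching of
consensus genotypes. Parentage is pairwise: Mendelian exclusion (opposing
homozygotes) combined with a single-parent likelihood-ratio (LOD) score in
which the unknown second parent is integrated over Hardy-Weinberg genotype
frequencies and a per-locus genotyping-error rate epsilon mixes the Mendelian
transition with the unconditional HWE genotype probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix, MarkerDef, PanelError, Pedigree

DEFAULT_PID_THRESHOLD = 1e-4  # the "natural populations" PID threshold
DEFAULT_EPSILON = 1e-4  # per-locus genotyping error assumed for consensus data
DEFAULT_MAX_MISMATCH = 3
DEFAULT_MAX_EXCLUSIONS = 1


def allele_frequencies(gm: GenotypeMatrix, markers: list,
                       group: str | None = None) -> pd.DataFrame:
    """Per-marker allele frequencies from called genotypes.

    Returns a frame indexed by marker id with columns ``freq_a``, ``freq_b``
    (frequency of allele_a / allele_b), ``n_copies`` (called gene copies) and
    ``h_e`` (expected heterozygosity 1 - sum p_i^2).
    """
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    sub = gm
    if group is not None:
        keep = gm.labels.index[gm.labels["line"] == group]
        sub = GenotypeMatrix(gm.genotypes.loc[keep], gm.labels.loc[keep])
    dos = sub.dosage(auto)
    rows = {}
    for m in auto:
        col = dos[m.marker_id].dropna()
        n_copies = 2 * len(col)
        if n_copies == 0:
            rows[m.marker_id] = {"freq_a": np.nan, "freq_b": np.nan, "n_copies": 0,
                                 "h_e": np.nan}
            continue
        q = float(col.sum()) / n_copies
        p = 1.0 - q
        rows[m.marker_id] = {"freq_a": p, "freq_b": q, "n_copies": n_copies,
                             "h_e": 1.0 - (p * p + q * q)}
    return pd.DataFrame.from_dict(rows, orient="index")


def pid_single_locus(p: np.ndarray) -> float:
    """PID at one locus: sum p_i^4 + sum_{i<j} (2 p_i p_j)^2."""
    p = np.asarray(p, dtype=float)
    out = float(np.sum(p ** 4))
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            out += (2 * p[i] * p[j]) ** 2
    return out


def pidsib_single_locus(p: np.ndarray) -> float:
    """PIDsib at one locus: 0.25 + 0.5 S2 + 0.5 S2^2 - 0.25 S4."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4


@dataclass
class PidCurve:
    table: pd.DataFrame  # per locus (sorted by descending H_E): cumulative curves
    threshold: float
    loci_to_pid: int | None  # locus count where cum PID first <= threshold
    loci_to_pidsib: int | None


def pid_curves(freqs: pd.DataFrame, threshold: float = DEFAULT_PID_THRESHOLD) -> PidCurve:
    """Cumulative PID / PIDsib curves over loci sorted by descending H_E.

    Accumulation is done in log space so the curves stay meaningful far past
    the underflow point of a naive product.
    """
    f = freqs.dropna(subset=["h_e"]).sort_values("h_e", ascending=False)
    if f.empty or (f["h_e"] <= 0).all():
        warnings.warn("no polymorphic markers: PID curves are constant at 1")
    rows = []
    log_pid = 0.0
    log_sib = 0.0
    loci_pid = loci_sib = None
    for k, (mid, row) in enumerate(f.iterrows(), start=1):
        p = np.array([row["freq_a"], row["freq_b"]])
        pid_l = pid_single_locus(p)
        sib_l = pidsib_single_locus(p)
        log_pid += np.log10(pid_l)
        log_sib += np.log10(sib_l)
        if loci_pid is None and log_pid <= np.log10(threshold):
            loci_pid = k
        if loci_sib is None and log_sib <= np.log10(threshold):
            loci_sib = k
        rows.append({"marker_id": mid, "h_e": row["h_e"], "pid_locus": pid_l,
                     "pidsib_locus": sib_l, "cum_pid": 10 ** log_pid,
                     "cum_pidsib": 10 ** log_sib, "log10_cum_pid": log_pid,
                     "log10_cum_pidsib": log_sib})
    return PidCurve(pd.DataFrame(rows), threshold, loci_pid, loci_sib)


@dataclass
class MismatchMatrix:
    mismatches: pd.DataFrame  # individual x individual mismatch counts
    compared: pd.DataFrame  # loci compared per pair
    groups: list  # candidate same-individual groups (lists of ids)
    incomparable: list  # pairs with zero shared called loci


def match_individuals(gm: GenotypeMatrix, markers: list,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH) -> MismatchMatrix:
    """Pairwise allele-mismatch counts and candidate same-individual groups.

    A mismatch is a locus called in both individuals whose unordered genotypes
    differ. Samples whose pairwise mismatch count is <= ``max_mismatch`` are
    linked; connected components form the match groups.
    """
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    dos = gm.dosage(auto).to_numpy()
    ids = gm.individuals
    n = len(ids)
    called = ~np.isnan(dos)
    both = called[:, None, :] & called[None, :, :]
    with np.errstate(invalid="ignore"):
        diff = (dos[:, None, :] != dos[None, :, :]) & both
    mism = diff.sum(axis=2)
    comp = both.sum(axis=2)
    np.fill_diagonal(mism, 0)
    mm = pd.DataFrame(mism, index=ids, columns=ids)
    cp = pd.DataFrame(comp, index=ids, columns=ids)

    g = nx.Graph()
    g.add_nodes_from(ids)
    incomparable = []
    for i in range(n):
        for j in range(i + 1, n):
            if comp[i, j] == 0:
                incomparable.append((ids[i], ids[j]))
            elif mism[i, j] <= max_mismatch:
                g.add_edge(ids[i], ids[j])
    groups = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    return MismatchMatrix(mm, cp, sorted(groups), incomparable)


# ---------------------------------------------------------------------------
# parentage


def transition_matrix(q: float) -> np.ndarray:
    """Single-parent Mendelian transition T[g_parent, g_offspring].

    Genotypes are coded by allele_b dosage (0, 1, 2); the untyped second
    parent contributes an allele drawn from Hardy-Weinberg frequencies
    (p = 1 - q for allele_a).
    """
    p = 1.0 - q
    return np.array(
        [
            [p, q, 0.0],
            [p / 2, 0.5, q / 2],
            [0.0, p, q],
        ]
    )


def hwe_probs(q: float) -> np.ndarray:
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


@dataclass
class PoAssignment:
    """Pairwise parent-offspring candidate table for all focal individuals."""

    table: pd.DataFrame  # focal, candidate, pool, compared, exclusions, lod, decision
    epsilon: float
    max_exclusions: int
    lod_min: float

    def assigned_pairs(self) -> set:
        t = self.table
        ok = t[t["decision"].isin(["assigned", "ambiguous"])]
        return {frozenset((a, b)) for a, b in zip(ok["focal"], ok["candidate"])}


def assign_parents(gm: GenotypeMatrix, freqs: pd.DataFrame, markers: list,
                   epsilon: float = DEFAULT_EPSILON,
                   max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
                   lod_min: float = 0.0) -> PoAssignment:
    """Pairwise PO screening of every individual against every other.

    Per candidate: exclusion count (loci with opposing homozygotes) and
    LOD = sum over called shared loci of
    log10( ((1-eps) T(g_o | g_c) + eps P_HW(g_o)) / P_HW(g_o) ).
    A candidate is ``assigned`` iff exclusions <= max_exclusions and
    LOD > lod_min; equal-LOD passing candidates in the same sex pool are
    ``ambiguous``. Orientation (who is the parent) is not determined.
    """
    if not 0 <= epsilon < 0.5:
        raise PanelError("epsilon must be in [0, 0.5)")
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns
            and m.marker_id in freqs.index]
    mids = [m.marker_id for m in auto]
    dos = gm.dosage(auto).to_numpy()
    ids = gm.individuals
    sexes = gm.labels["sex"].reindex(ids).fillna("U")
    n, n_loci = dos.shape
    q = freqs.loc[mids, "freq_b"].to_numpy()

    # per-locus 3x3 log10 likelihood-ratio lookup, [g_candidate, g_offspring]
    ratio = np.empty((3, 3, n_loci))
    hw = np.empty((3, n_loci))
    for l in range(n_loci):
        t = transition_matrix(q[l])
        h = hwe_probs(q[l])
        hw[:, l] = h
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio[:, :, l] = np.log10(((1 - epsilon) * t + epsilon * h[None, :]) / h[None, :])
    ratio = np.nan_to_num(ratio, nan=0.0, posinf=0.0, neginf=-np.inf)

    code = np.where(np.isnan(dos), -1, dos).astype(int)
    called = code >= 0
    loc_idx = np.arange(n_loci)
    rows = []
    for i in range(n):
        go = code[i]
        mask = called & called[i][None, :]  # (n, L): both called
        gc = code
        lod_terms = ratio[np.clip(gc, 0, 2), np.clip(go, 0, 2)[None, :], loc_idx[None, :]]
        lod = np.where(mask, lod_terms, 0.0).sum(axis=1)
        excl = (mask & (((gc == 0) & (go[None, :] == 2)) | ((gc == 2) & (go[None, :] == 0)))).sum(axis=1)
        compared = mask.sum(axis=1)
        for j in range(n):
            if i == j:
                continue  # an individual cannot be its own parent
            if compared[j] == 0:
                rows.append({"focal": ids[i], "candidate": ids[j], "pool": "U",
                             "compared": 0, "exclusions": 0, "lod": np.nan,
                             "decision": "skipped"})
                continue
            pool = {"M": "sire", "F": "dam"}.get(sexes.iloc[j], "U")
            passes = excl[j] <= max_exclusions and lod[j] > lod_min
            rows.append({"focal": ids[i], "candidate": ids[j], "pool": pool,
                         "compared": int(compared[j]), "exclusions": int(excl[j]),
                         "lod": float(lod[j]),
                         "decision": "assigned" if passes else "rejected"})
    table = pd.DataFrame(rows)
    # equal-LOD ties among passing candidates of the same pool -> ambiguous
    for (focal, pool), grp in table[table["decision"] == "assigned"].groupby(["focal", "pool"]):
        dup = grp["lod"].round(9).duplicated(keep=False)
        if dup.any():
            table.loc[grp.index[dup], "decision"] = "ambiguous"
    return PoAssignment(table, epsilon, max_exclusions, lod_min)


@dataclass
class FamilyNetwork:
    graph: nx.Graph  # assigned PO edges, labelled by concordance category
    counts: dict  # verified / not_verified / not_testable / novel
    edges: pd.DataFrame


def build_family_network(po: PoAssignment, pedigree: Pedigree | None = None,
                         genotyped: set | None = None) -> FamilyNetwork:
    """Assemble assigned PO links into a network and reconcile with a pedigree.

    Expected (studbook) PO links are labelled ``verified`` when genetically
    assigned, ``not_verified`` when both members are genotyped but the link
    was not assigned, and ``not_testable`` when a member lacks a genotype;
    assigned links absent from the pedigree are ``novel``.
    """
    assigned = po.assigned_pairs()
    if genotyped is None:
        genotyped = set(po.table["focal"]) | set(po.table["candidate"])
    g = nx.Graph()
    rows = []
    counts = {"verified": 0, "not_verified": 0, "not_testable": 0, "novel": 0}
    expected = pedigree.po_pairs() if pedigree is not None else set()
    for pair in expected:
        a, b = sorted(pair)
        if not (a in genotyped and b in genotyped):
            counts["not_testable"] += 1
            rows.append({"a": a, "b": b, "category": "not_testable"})
            continue
        cat = "verified" if pair in assigned else "not_verified"
        counts[cat] += 1
        rows.append({"a": a, "b": b, "category": cat})
        if cat == "verified":
            g.add_edge(a, b, category=cat)
    for pair in assigned - expected:
        a, b = sorted(pair)
        counts["novel"] += 1
        rows.append({"a": a, "b": b, "category": "novel"})
        g.add_edge(a, b, category="novel")
    return FamilyNetwork(g, counts, pd.DataFrame(rows))
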