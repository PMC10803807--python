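"""Breeding-line assignment and cross-species detection.

Two independent clustering routes feed a dual-threshold decision rule: an
unsupervised classification-EM under a Hardy-Weinberg-within-cluster
likelihood (with BIC over a K grid), and a supervised leave-one-out
assignment with Dirichlet(1) posterior-predictive genotype probabilities per
reference line. An individual is assigned to a breeding line only when both
methods give that line at least the threshold probability (default 60%).

Cross-species detection gates individuals on panel call rate and ordinates
the survivors by principal coordinates analysis of the codominant squared
genetic distance (0/1/4 per locus, i.e. squared allele-dosage difference),
rescaled for missingness by the shared-locus fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix, PanelError

DEFAULT_THRESHOLD = 0.60
DEFAULT_CALL_RATE_MIN = 0.80
_FREQ_CLIP = 1e-6


@dataclass
class MembershipResult:
    q: pd.DataFrame  # individuals x clusters membership probabilities
    method: str  # ml_em | bayes_af
    log_likelihood: float
    bic: float | None = None
    cluster_freqs: pd.DataFrame | None = None  # cluster x locus allele-b freq
    converged: bool = True
    loglik_trajectory: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.q.shape[1]


def _dosage_indicators(gm: GenotypeMatrix, markers: list):
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    dos = gm.dosage(auto).to_numpy()
    called = ~np.isnan(dos)
    code = np.where(called, dos, 0).astype(int)
    ind = np.stack([(code == g) & called for g in range(3)])  # (3, n, L)
    return auto, dos, called, ind


def _hwe_loglik(ind, freqs):
    """Per-individual log-likelihood under HWE at given allele-b freqs.

    ind: (3, n, L) genotype indicators; freqs: (K, L). Returns (n, K).
    """
    q = np.clip(freqs, _FREQ_CLIP, 1 - _FREQ_CLIP)
    p = 1 - q
    logg = np.stack([2 * np.log(p), np.log(2 * p * q), 2 * np.log(q)])  # (3, K, L)
    # sum over genotype classes and loci
    return np.einsum("gnl,gkl->nk", ind.astype(float), logg)


def ml_cluster(gm: GenotypeMatrix, markers: list, k: int, seed: int = 0,
               n_starts: int = 20, max_iter: int = 200) -> MembershipResult:
    """Classification EM under a HWE-within-cluster genotype likelihood.

    The E-step assigns each individual to the cluster maximising its genotype
    likelihood; the M-step re-estimates cluster allele frequencies from the
    assigned individuals. Membership Q is the row-normalised per-cluster
    likelihood at convergence. Multi-start with a deterministic seed schedule
    (dosage k-means-style centroid start plus random restarts); the best
    classification likelihood wins. BIC = -2 logL + K*L*log(n).
    """
    if k < 1:
        raise PanelError("k must be >= 1")
    auto, dos, called, ind = _dosage_indicators(gm, markers)
    n, n_loci = dos.shape
    ids = gm.individuals
    mids = [m.marker_id for m in auto]

    def m_step(z):
        freqs = np.empty((k, n_loci))
        for c in range(k):
            sel = z == c
            cnt = np.nansum(np.where(called[sel], dos[sel], 0.0), axis=0)
            tot = 2 * called[sel].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs[c] = np.where(tot > 0, cnt / np.maximum(tot, 1), 0.5)
        return freqs

    best = None
    rng_master = np.random.default_rng(seed)
    start_seeds = rng_master.integers(0, 2 ** 31 - 1, size=n_starts)
    imputed = np.where(called, dos, np.nanmean(np.where(called, dos, np.nan), axis=0))
    for s_idx, s in enumerate(start_seeds):
        rng = np.random.default_rng(s)
        if s_idx == 0 and k > 1:
            # centroid-style start: seed clusters from k distant individuals
            centers = [int(rng.integers(n))]
            for _ in range(k - 1):
                d = np.min(
                    [np.sum((imputed - imputed[c]) ** 2, axis=1) for c in centers], axis=0
                )
                centers.append(int(np.argmax(d)))
            z = np.argmin(
                np.stack([np.sum((imputed - imputed[c]) ** 2, axis=1) for c in centers]),
                axis=0,
            )
        else:
            z = rng.integers(k, size=n)
        traj = []
        converged = False
        for _ in range(max_iter):
            for c in range(k):  # keep every cluster populated
                if not (z == c).any():
                    z[rng.integers(n)] = c
            freqs = m_step(z)
            ll = _hwe_loglik(ind, freqs)
            z_new = ll.argmax(axis=1)
            traj.append(float(ll.max(axis=1).sum()))
            if (z_new == z).all():
                converged = True
                break
            z = z_new
        total = traj[-1]
        if best is None or total > best[0]:
            best = (total, z, freqs, ll, traj, converged)

    total, z, freqs, ll, traj, converged = best
    # normalised per-cluster likelihoods as membership probabilities
    q = np.exp(ll - ll.max(axis=1, keepdims=True))
    q /= q.sum(axis=1, keepdims=True)
    # BIC is computed from the equal-weight mixture log-likelihood: the
    # classification (max-assignment) likelihood is not a proper model
    # likelihood and would systematically favour larger K
    mix = ll - np.log(k)
    mmax = mix.max(axis=1, keepdims=True)
    mix_ll = float((mmax[:, 0] + np.log(np.exp(mix - mmax).sum(axis=1))).sum())
    bic = -2 * mix_ll + k * n_loci * np.log(n)
    return MembershipResult(
        pd.DataFrame(q, index=ids, columns=[f"cluster{c}" for c in range(k)]),
        "ml_em", total, bic,
        pd.DataFrame(freqs, index=[f"cluster{c}" for c in range(k)], columns=mids),
        converged, traj,
    )


def select_k(gm: GenotypeMatrix, markers: list, k_range=range(1, 11),
             seed: int = 0, n_starts: int = 10) -> tuple:
    """Fit ml_cluster over a K grid; returns (best_k, {k: MembershipResult})."""
    fits = {k: ml_cluster(gm, markers, k, seed=seed + k, n_starts=n_starts)
            for k in k_range}
    best_k = min(fits, key=lambda k: fits[k].bic)
    return best_k, fits


def bayes_assign(gm: GenotypeMatrix, markers: list,
                 reference: pd.Series | None = None) -> MembershipResult:
    """Supervised leave-one-out line assignment.

    For each focal individual and each reference line, allele counts are
    taken from that line's reference genotypes excluding the focal individual
    itself; with a symmetric Dirichlet(1) prior the posterior-predictive
    probability of the focal genotype (two draws without replacement from the
    Dirichlet-multinomial) is multiplied over called loci. Q is the
    row-normalised marginal likelihood across lines. Loci with no reference
    genotypes for a line are skipped for that line.
    """
    if reference is None:
        reference = gm.labels["line"]
    lines = sorted(set(reference) - {"U"})
    if len(lines) < 2:
        raise PanelError("need at least two labelled reference lines")
    auto, dos, called, _ = _dosage_indicators(gm, markers)
    ids = gm.individuals
    n, n_loci = dos.shape
    ref = reference.reindex(ids).fillna("U").to_numpy()

    loglik = np.zeros((n, len(lines)))
    for gi, line in enumerate(lines):
        members = ref == line
        cnt_b = np.where(called & members[:, None], dos, 0.0).sum(axis=0)
        cnt_tot = 2.0 * (called & members[:, None]).sum(axis=0)
        for i in range(n):
            if members[i]:
                nb = cnt_b - np.where(called[i], dos[i], 0.0)
                nt = cnt_tot - 2.0 * called[i]
            else:
                nb, nt = cnt_b, cnt_tot
            na = nt - nb
            usable = called[i] & (nt > 0)
            a1, b1 = na + 1.0, nb + 1.0
            tot2 = (nt + 2.0) * (nt + 3.0)
            pg = np.select(
                [dos[i] == 0, dos[i] == 1],
                [a1 * (a1 + 1) / tot2, 2 * a1 * b1 / tot2],
                default=b1 * (b1 + 1) / tot2,
            )
            loglik[i, gi] = np.log(pg[usable]).sum()
    q = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    q /= q.sum(axis=1, keepdims=True)
    return MembershipResult(pd.DataFrame(q, index=ids, columns=lines),
                            "bayes_af", float(loglik.max(axis=1).sum()))


def align_to_lines(m: MembershipResult, reference: pd.Series) -> MembershipResult:
    """Rename anonymous clusters to line labels via labelled anchor individuals."""
    lines = sorted(set(reference) - {"U"})
    if not lines:
        raise PanelError("no labelled anchors to align clusters to lines")
    if set(m.q.columns) >= set(lines):
        return m  # already line-labelled (supervised route)
    anchors = reference[reference.isin(lines)]
    if anchors.empty:
        raise PanelError("no labelled anchors to align clusters to lines")
    if len(lines) != m.k:
        raise PanelError(f"cannot align {m.k} clusters to {len(lines)} lines")
    # choose the cluster->line bijection maximising mean anchor membership
    from itertools import permutations

    qa = m.q.loc[m.q.index.intersection(anchors.index)]
    ref = anchors.loc[qa.index]
    best, best_score = None, -np.inf
    for perm in permutations(m.q.columns):
        score = sum(qa.loc[ref == line, col].sum() for line, col in zip(lines, perm))
        if score > best_score:
            best, best_score = perm, score
    renamed = m.q[list(best)].copy()
    renamed.columns = lines
    return MembershipResult(renamed, m.method, m.log_likelihood, m.bic,
                            m.cluster_freqs, m.converged, m.loglik_trajectory)


def decide_lines(m1: MembershipResult, m2: MembershipResult,
                 threshold: float = DEFAULT_THRESHOLD,
                 expected: pd.Series | None = None) -> pd.DataFrame:
    """Dual-threshold line decisions.

    A line is assigned iff both methods give it membership >= ``threshold``;
    otherwise the individual is unassigned with a reason flag
    (``below_threshold`` or ``method_conflict``). When expected labels are
    supplied, each decision is compared (match / false_positive / n/a).
    """
    common = [c for c in m1.q.columns if c in m2.q.columns]
    if len(common) < 2:
        raise PanelError("membership results do not share aligned line labels")
    ids = m1.q.index
    rows = []
    for iid in ids:
        q1 = m1.q.loc[iid, common]
        q2 = m2.q.loc[iid, common]
        top1, top2 = q1.idxmax(), q2.idxmax()
        decision, flag = "unassigned", ""
        if q1[top1] >= threshold and q2[top2] >= threshold:
            if top1 == top2:
                decision, flag = top1, "concordant"
            else:
                flag = "method_conflict"
        else:
            flag = "below_threshold"
        rec = {"individual": iid, "decision": decision, "flag": flag,
               **{f"q1_{c}": float(q1[c]) for c in common},
               **{f"q2_{c}": float(q2[c]) for c in common}}
        if expected is not None:
            exp = expected.get(iid, "U")
            if decision == "unassigned" or exp in ("U", None):
                rec["comparison"] = "n/a"
            else:
                rec["comparison"] = "match" if decision == exp else "false_positive"
        rows.append(rec)
    return pd.DataFrame(rows).set_index("individual")


# ---------------------------------------------------------------------------
# cross-species PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    percent_variance: np.ndarray  # per positive axis
    included: list
    excluded: pd.DataFrame  # individuals below the call-rate gate


def genetic_distance_matrix(gm: GenotypeMatrix, markers: list) -> pd.DataFrame:
    """Codominant squared distance: per locus (dosage_i - dosage_j)^2, summed
    over shared called loci and rescaled by total / shared loci."""
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    dos = gm.dosage(auto).to_numpy()
    called = ~np.isnan(dos)
    x = np.where(called, dos, 0.0)
    n_loci = dos.shape[1]
    shared = called.astype(float) @ called.astype(float).T
    diff2 = np.zeros((len(dos), len(dos)))
    for i in range(len(dos)):
        both = called[i][None, :] & called
        d = np.where(both, (x[i][None, :] - x) ** 2, 0.0)
        diff2[i] = d.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(shared > 0, diff2 * (n_loci / shared), np.nan)
    np.fill_diagonal(scaled, 0.0)
    return pd.DataFrame(scaled, index=gm.individuals, columns=gm.individuals)


def pcoa_from_squared_distances(d2: pd.DataFrame) -> PcoaResult:
    """Classical PCoA: double-centre -0.5 * D2 and eigendecompose.

    Negative eigenvalues (non-Euclidean distances) are reported, not dropped;
    coordinates use the positive axes only.
    """
    a = -0.5 * d2.to_numpy(dtype=float)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pct = 100 * vals[pos] / vals[pos].sum()
    cols = [f"axis{i + 1}" for i in range(pos.sum())]
    return PcoaResult(pd.DataFrame(coords, index=d2.index, columns=cols),
                      vals, pct, list(d2.index), pd.DataFrame())


def species_pcoa(gm: GenotypeMatrix, markers: list,
                 call_rate_min: float = DEFAULT_CALL_RATE_MIN) -> PcoaResult:
    """Call-rate-gated PCoA for cross-species discrimination.

    Individuals with a call rate below ``call_rate_min`` over the supplied
    loci are excluded and listed in the result.
    """
    auto = [m for m in markers if m.is_autosomal and m.marker_id in gm.genotypes.columns]
    sub = gm.restrict(auto)
    cr = sub.call_rate()
    keep = cr.index[cr >= call_rate_min]
    excluded = pd.DataFrame({"call_rate": cr[cr < call_rate_min]})
    if len(keep) < 3:
        raise PanelError("fewer than 3 individuals pass the call-rate gate")
    kept = GenotypeMatrix(sub.genotypes.loc[keep], sub.labels.loc[keep])
    d2 = genetic_distance_matrix(kept, auto)
    res = pcoa_from_squared_distances(d2)
    res.excluded = excluded
    return res
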