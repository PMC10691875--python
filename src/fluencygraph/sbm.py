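"""Degree-corrected stochastic block model over the similarity graph.

The weighted cosine-similarity graph is discretized into a multigraph by
quantile-binning the edge weights into ``Q`` integer multiplicities; the
partition of participants into blocks is then scored by a microcanonical
description length (DL, in nats) composed of

* the degree-corrected block-adjacency entropy of the multigraph,
* a Gaussian term per block pair for each standardized edge covariate
  (absolute age and NART differences), with a BIC-style parameter cost,
* model costs for the partition itself, the block edge-count matrix and the
  block-wise degree sequences.

Inference minimizes the DL by agglomerative merges from the singleton
partition down a block-count ladder, followed by single-node Metropolis
sweeps that accept DL decreases always and DL increases with probability
``exp(-dDL)``. The best state visited is returned; an optional second
hierarchy level re-fits the model to the block-level multigraph.

The exact DL value is implementation-defined (no attempt is made to match
any third-party nested-SBM code number for number); what matters is that
lower is better and that comparisons between partitions of the same graph
are meaningful.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from .cohort import Participant
from .embedding import SimilarityGraph
from .scoring import ScoreCard, Transcript

__all__ = [
    "BlockPartition",
    "CommunityProfile",
    "quantile_bin_weights",
    "assignment_dl",
    "fit_sbm",
    "compare_partitions",
    "profile_communities",
    "community_contrasts",
]

# Variance floor for the standardized edge-covariate likelihoods. Absolute
# node-attribute differences carry genuine continuous fine structure, so an
# unfloored per-pair Gaussian would reward splitting blocks until every pair
# is attribute-homogeneous; flooring the variance at (0.5 SD)^2 bounds the
# per-pair likelihood gain and keeps the connectivity evidence in charge.
_VAR_FLOOR = 0.25


@dataclass
class BlockPartition:
    """Community assignment with its description length."""

    participant_ids: list[str]
    assignment: np.ndarray
    n_blocks: int
    description_length: float
    hierarchy: Optional[list[np.ndarray]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (len(self.participant_ids),):
            raise ValueError("assignment length mismatch")
        if not np.isfinite(self.description_length):
            raise ValueError("description length must be finite")
        if self.hierarchy:
            fine = self.assignment
            for coarse in self.hierarchy:
                for blk in np.unique(fine):
                    if len(np.unique(coarse[fine == blk])) != 1:
                        raise ValueError("hierarchy levels must nest")
                fine = np.asarray(coarse)

    def blocks(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, blk in zip(self.participant_ids, self.assignment):
            out.setdefault(int(blk), []).append(pid)
        return out


def quantile_bin_weights(W: np.ndarray, Q: int = 8) -> np.ndarray:
    """Discretize edge weights into integer multiplicities 0..Q-1.

    The multiplicity of an edge is the number of weight quantiles (at
    1/Q .. (Q-1)/Q of the off-diagonal weight distribution) strictly below
    its weight, so the weakest edges vanish and the strongest carry Q-1
    parallel edges.
    """
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = W[iu]
    edges = np.quantile(vals, np.arange(1, Q) / Q)
    mult = (vals[:, None] > edges[None, :]).sum(axis=1)
    M = np.zeros((n, n), dtype=np.int64)
    M[iu] = mult
    return M + M.T


def _lbinom(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _xlogx(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x * np.log(np.maximum(x, 1e-300)), 0.0)


class _Aggregates:
    """Block-level sufficient statistics of a partition (ordered-pair
    convention: diagonal entries count within-block pairs twice)."""

    __slots__ = ("m", "nr", "S", "SS")

    def __init__(self, m: np.ndarray, nr: np.ndarray,
                 S: list[np.ndarray], SS: list[np.ndarray]):
        self.m, self.nr, self.S, self.SS = m, nr, S, SS

    @classmethod
    def from_assignment(cls, M: np.ndarray, covs: Sequence[np.ndarray],
                        b: np.ndarray, B: int) -> "_Aggregates":
        n = M.shape[0]
        P = np.zeros((n, B))
        P[np.arange(n), b] = 1.0
        m = P.T @ M @ P
        S = [P.T @ C @ P for C in covs]
        SS = [P.T @ (C * C) @ P for C in covs]
        nr = np.bincount(b, minlength=B).astype(float)
        return cls(m, nr, S, SS)

    def copy(self) -> "_Aggregates":
        return _Aggregates(self.m.copy(), self.nr.copy(),
                           [s.copy() for s in self.S], [s.copy() for s in self.SS])

    def merge(self, r: int, s: int) -> "_Aggregates":
        """Aggregates after merging block s into block r (s removed)."""
        keep = [i for i in range(len(self.nr)) if i != s]

        def fold(A: np.ndarray) -> np.ndarray:
            A2 = A.copy()
            A2[r, :] += A2[s, :]
            A2[:, r] += A2[:, s]
            return A2[np.ix_(keep, keep)]

        nr = self.nr.copy()
        nr[r] += nr[s]
        return _Aggregates(fold(self.m), nr[keep],
                           [fold(x) for x in self.S], [fold(x) for x in self.SS])

    def apply_move(self, r: int, s: int, nbm: np.ndarray,
                   nbc: list[np.ndarray], nbc2: list[np.ndarray]) -> "_Aggregates":
        """Aggregates after moving one node from block r to block s; the
        nb* vectors hold the node's edge/covariate sums to each block."""
        out = self.copy()

        def shift(A: np.ndarray, v: np.ndarray) -> None:
            A[r, :] -= v
            A[:, r] -= v
            A[s, :] += v
            A[:, s] += v

        shift(out.m, nbm)
        for S, v in zip(out.S, nbc):
            shift(S, v)
        for SS, v in zip(out.SS, nbc2):
            shift(SS, v)
        out.nr[r] -= 1
        out.nr[s] += 1
        return out


def _dl(agg: _Aggregates, N: int, E: float, lnfact_k: float) -> float:
    m, nr = agg.m, agg.nr
    if np.any(nr < 1):  # states with emptied blocks are never preferred
        return float("inf")
    B = len(nr)
    e = m.sum(axis=1)
    # degree-corrected multigraph entropy
    S_e = -E - lnfact_k - 0.5 * _xlogx(m).sum() + _xlogx(e).sum()
    # partition, edge-matrix and degree-sequence model costs
    L_part = (np.log(N) + _lbinom(N - 1, B - 1)
              + gammaln(N + 1) - gammaln(nr + 1).sum())
    L_edge = _lbinom(B * (B + 1) / 2 + E - 1, E)
    L_deg = np.sum(_lbinom(nr + e - 1, e))
    dl = S_e + L_part + L_edge + L_deg
    # Gaussian block-pair likelihood for each standardized edge covariate
    npair = nr[:, None] * nr[None, :]
    np.fill_diagonal(npair, nr * (nr - 1))
    pos = npair > 0
    for S, SS in zip(agg.S, agg.SS):
        mean = np.where(pos, S / np.maximum(npair, 1), 0.0)
        var = np.where(pos, SS / np.maximum(npair, 1) - mean ** 2, 0.0)
        var = np.maximum(var, 0.0) + _VAR_FLOOR
        nll = 0.5 * npair * (np.log(2 * np.pi * var) + 1.0)
        pen = np.where(pos, np.log(npair / 2.0 + 1.0), 0.0)
        dl += 0.5 * float((nll + pen)[pos].sum())
    return float(dl)


def _compress(b: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel blocks to 0..B-1 in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(b)
    for i, blk in enumerate(b):
        if blk not in mapping:
            mapping[blk] = len(mapping)
        out[i] = mapping[blk]
    return out, len(mapping)


def _fit_binned(M: np.ndarray, covs: Sequence[np.ndarray],
                rng: np.random.Generator, max_blocks: int,
                n_sweeps: int) -> tuple[np.ndarray, float]:
    """Minimize the DL of a binned multigraph; returns (assignment, DL)."""
    n = M.shape[0]
    k = M.sum(axis=1)
    E = float(M.sum()) / 2.0
    lnfact_k = float(gammaln(k + 1).sum())

    def dl_of(agg: _Aggregates) -> float:
        return _dl(agg, n, E, lnfact_k)

    b = np.arange(n)
    agg = _Aggregates.from_assignment(M, covs, b, n)
    ladder: list[tuple[float, np.ndarray]] = [(dl_of(agg), b.copy())]

    # agglomerative phase: merge connected block pairs down to one block
    while len(agg.nr) > 1:
        B = len(agg.nr)
        iu = np.triu_indices(B, k=1)
        conn = agg.m[iu].astype(float) + 1e-6
        n_cand = min(len(conn), max(20, 2 * B))
        cand = rng.choice(len(conn), size=n_cand, replace=False, p=conn / conn.sum())
        base = dl_of(agg)
        scored = sorted(
            (dl_of(agg.merge(int(iu[0][c]), int(iu[1][c]))) - base,
             int(iu[0][c]), int(iu[1][c]))
            for c in cand
        )
        n_apply = max(1, int(0.25 * B)) if B > 2 else 1
        touched: set[int] = set()
        merges = []
        for _, r, s in scored:
            if r in touched or s in touched:
                continue
            merges.append((r, s))
            touched.update((r, s))
            if len(merges) >= n_apply:
                break
        # apply the selected disjoint merges via a block relabelling
        labels = np.arange(B)
        for r, s in merges:
            labels[s] = r
        labels, _ = _compress(labels)
        b = labels[b]
        agg = _Aggregates.from_assignment(M, covs, b, int(labels.max()) + 1)
        ladder.append((dl_of(agg), b.copy()))

    # Metropolis refinement of the most promising ladder states
    eligible = [(dl, st) for dl, st in ladder if len(np.unique(st)) <= max_blocks]
    eligible.sort(key=lambda t: t[0])
    best_dl, best_b = eligible[0][0], eligible[0][1].copy()
    for dl0, state in eligible[:3]:
        b = state.copy()
        b, B = _compress(b)
        agg = _Aggregates.from_assignment(M, covs, b, B)
        cur = dl_of(agg)
        for _ in range(n_sweeps):
            if len(agg.nr) < 2:
                break
            for i in rng.permutation(n):
                B = len(agg.nr)
                r = int(b[i])
                nbm = np.bincount(b, weights=M[i], minlength=B)
                nbc = [np.bincount(b, weights=C[i], minlength=B) for C in covs]
                nbc2 = [np.bincount(b, weights=C[i] * C[i], minlength=B) for C in covs]
                targets = [s for s in range(B) if s != r]
                deltas = []
                for s in targets:
                    trial = agg.apply_move(r, s, nbm, nbc, nbc2)
                    deltas.append((dl_of(trial), s, trial))
                deltas.sort(key=lambda t: t[0])
                new_dl, s, trial = deltas[0]
                d = new_dl - cur
                if d < 0 or rng.random() < np.exp(-min(d, 50.0)):
                    agg, cur = trial, new_dl
                    b[i] = s
                    if agg.nr[r] == 0:  # block emptied: drop and relabel
                        b, B = _compress(b)
                        agg = _Aggregates.from_assignment(M, covs, b, B)
                        cur = dl_of(agg)
                    if cur < best_dl:
                        best_dl, best_b = cur, b.copy()
    best_b, _ = _compress(best_b)
    return best_b, float(best_dl)


def assignment_dl(G: SimilarityGraph, assignment: np.ndarray, Q: int = 8) -> float:
    """Description length of an arbitrary assignment of ``G`` (for
    comparisons against fitted partitions; same binning and covariates)."""
    M = quantile_bin_weights(G.weights, Q=Q)
    covs = _standardized_covariates(G)
    b, B = _compress(np.asarray(assignment, dtype=int))
    agg = _Aggregates.from_assignment(M, covs, b, B)
    k = M.sum(axis=1)
    return _dl(agg, M.shape[0], float(M.sum()) / 2.0, float(gammaln(k + 1).sum()))


def _standardized_covariates(G: SimilarityGraph) -> list[np.ndarray]:
    covs = []
    n = G.n
    iu = np.triu_indices(n, k=1)
    for name in sorted(G.edge_covariates):
        C = np.asarray(G.edge_covariates[name], dtype=float)
        vals = C[iu]
        sd = vals.std()
        Cz = (C - vals.mean()) / (sd if sd > 0 else 1.0)
        np.fill_diagonal(Cz, 0.0)
        covs.append(Cz)
    return covs


def fit_sbm(G: SimilarityGraph, max_blocks: int = 25, n_sweeps: int = 10,
            seed: int = 0, Q: int = 8, hierarchy: bool = True) -> BlockPartition:
    """Fit the degree-corrected SBM to a similarity graph by DL minimization.

    ``max_blocks`` caps the partitions considered in the refinement stage
    (a warning is issued if the best state sits at the cap); ``n_sweeps``
    Metropolis sweeps polish each candidate state. Deterministic under
    ``seed``.
    """
    if G.n < 4:
        raise ValueError("need at least 4 nodes to fit a block model")
    rng = np.random.default_rng(seed)
    M = quantile_bin_weights(G.weights, Q=Q)
    covs = _standardized_covariates(G)
    b, dl = _fit_binned(M, covs, rng, max_blocks=max_blocks, n_sweeps=n_sweeps)
    B = int(b.max()) + 1
    if B >= max_blocks:
        warnings.warn("best partition hit the max_blocks boundary", stacklevel=2)
    hier = None
    if hierarchy and B >= 4:
        P = np.zeros((G.n, B))
        P[np.arange(G.n), b] = 1.0
        m_block = np.rint(P.T @ M @ P).astype(np.int64)
        np.fill_diagonal(m_block, 0)
        cb, _ = _fit_binned(m_block, [], np.random.default_rng(seed + 1),
                            max_blocks=max(2, B - 1), n_sweeps=n_sweeps)
        if len(np.unique(cb)) < B:
            hier = [cb[b]]
    return BlockPartition(list(G.participant_ids), b, B, dl,
                          hierarchy=hier, seed=seed)


def compare_partitions(a: BlockPartition, b: BlockPartition) -> float:
    """Adjusted agreement (adjusted Rand index) between two partitions."""
    if set(a.participant_ids) != set(b.participant_ids):
        raise ValueError("partitions cover different participant sets")
    order = {pid: i for i, pid in enumerate(a.participant_ids)}
    b_aligned = np.empty_like(b.assignment)
    for pid, blk in zip(b.participant_ids, b.assignment):
        b_aligned[order[pid]] = blk
    return float(adjusted_rand_score(a.assignment, b_aligned))


@dataclass
class CommunityProfile:
    block: int
    n: int
    pct_by_group: dict[str, float]
    median_fluency: float
    median_age: float
    median_nart: float
    top_words: list[tuple[str, float]]


def profile_communities(
    partition: BlockPartition,
    participants: Sequence[Participant],
    transcripts: Sequence[Transcript],
    scorecards: Optional[Sequence[ScoreCard]] = None,
    top_n: int = 10,
) -> list[CommunityProfile]:
    """Characterize each community: group composition, medians and the most
    characteristic words by TF-IDF over community-level documents.

    Each community's document is the concatenation of its members' tokens;
    ``tf`` is the term count divided by the document length and ``idf`` is
    ``log(n_communities / n_communities containing the term)``. Ranking ties
    break alphabetically.
    """
    by_id = {p.participant_id: p for p in participants}
    t_by_id = {t.participant_id: t for t in transcripts}
    sc_by_id = {s.participant_id: s for s in scorecards} if scorecards else {}
    missing = set(partition.participant_ids) - set(by_id)
    if missing:
        raise ValueError(f"partition covers unknown participants: {sorted(missing)[:3]}")
    blocks = partition.blocks()
    docs = {blk: [tok for pid in pids for tok in t_by_id[pid].tokens]
            for blk, pids in blocks.items()}
    nonempty = {blk for blk, doc in docs.items() if doc}
    if len(nonempty) < len(docs):
        warnings.warn("dropping communities with empty documents", stacklevel=2)
    n_comm = len(nonempty)
    df_counts: Counter = Counter()
    for blk in nonempty:
        df_counts.update(set(docs[blk]))
    profiles = []
    for blk in sorted(nonempty):
        pids = blocks[blk]
        counts = Counter(docs[blk])
        doclen = len(docs[blk])
        scores = {
            w: (c / doclen) * np.log(n_comm / df_counts[w]) for w, c in counts.items()
        }
        top = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        members = [by_id[pid] for pid in pids]
        groups = Counter(p.group for p in members)
        flu = [sc_by_id[pid].correct_words for pid in pids if pid in sc_by_id]
        profiles.append(CommunityProfile(
            block=blk,
            n=len(pids),
            pct_by_group={g: 100.0 * groups.get(g, 0) / len(pids)
                          for g in sorted({p.group for p in participants})},
            median_fluency=float(np.median(flu)) if flu else float("nan"),
            median_age=float(np.median([p.age for p in members])),
            median_nart=float(np.median([p.nart for p in members])),
            top_words=[(w, float(s)) for w, s in top],
        ))
    return profiles


def community_contrasts(
    partition: BlockPartition,
    participants: Sequence[Participant],
    values: Optional[pd.DataFrame] = None,
    alpha_family: float = 0.05,
    divisor: int = 40,
) -> pd.DataFrame:
    """One-vs-rest community contrasts with a Bonferroni alpha/divisor rule.

    Continuous variables (``values`` columns, plus age and NART from the
    participant metadata) use two-sided Mann-Whitney U tests with normal
    approximation and tie correction; group-membership proportions use
    chi-square (Fisher's exact test when any expected count is below 5).
    """
    blocks = partition.blocks()
    if len(blocks) < 2:
        raise ValueError("need at least two communities to contrast")
    by_id = {p.participant_id: p for p in participants}
    cont = pd.DataFrame(index=list(partition.participant_ids))
    cont["age"] = [by_id[i].age for i in cont.index]
    cont["nart"] = [by_id[i].nart for i in cont.index]
    if values is not None:
        for col in values.columns:
            cont[col] = values.reindex(cont.index)[col]
    group_of = {i: by_id[i].group for i in cont.index}
    threshold = alpha_family / divisor
    rows = []
    for blk, pids in sorted(blocks.items()):
        mask = cont.index.isin(pids)
        for col in cont.columns:
            x, rest = cont.loc[mask, col].dropna(), cont.loc[~mask, col].dropna()
            if x.nunique() <= 1 and rest.nunique() <= 1 and set(x) == set(rest):
                rows.append((blk, col, "mannwhitney", np.nan, np.nan, threshold, False))
                continue
            u, p = mannwhitneyu(x, rest, alternative="two-sided", method="asymptotic")
            rows.append((blk, col, "mannwhitney", float(u), float(p), threshold,
                         bool(p < threshold)))
        for grp in sorted({g for g in group_of.values()}):
            in_grp = np.array([group_of[i] == grp for i in cont.index])
            table = np.array([
                [np.sum(mask & in_grp), np.sum(mask & ~in_grp)],
                [np.sum(~mask & in_grp), np.sum(~mask & ~in_grp)],
            ])
            if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                rows.append((blk, f"pct_{grp}", "chi2", np.nan, np.nan, threshold, False))
                continue
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if expected.min() < 5:
                _, p = fisher_exact(table)
                stat = np.nan
                test = "fisher"
            else:
                stat, p, _, _ = chi2_contingency(table, correction=False)
                test = "chi2"
            rows.append((blk, f"pct_{grp}", test, float(stat), float(p), threshold,
                         bool(p < threshold)))
    return pd.DataFrame(rows, columns=[
        "community", "variable", "test", "statistic", "p", "threshold", "significant",
    ])
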