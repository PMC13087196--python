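"""Mining of statistically significant time-ordered diagnosis trajectories.

A *trajectory* is an ordered tuple of ICD-10 blocks such that (i) the blocks
co-occur in patients more often than expected under independent carriage
(Jaccard coincidence, bootstrap test) and (ii) each consecutive pair shows a
significant temporal ordering (double one-tailed binomial tests, ties counted
against the tested direction).  Length-2 trajectories are significant directed
pairs; longer trajectories are assembled incrementally from overlapping
shorter ones, re-testing all orderings in the sub-population carrying every
member block.  All p-values are Holm step-down adjusted within explicit
families (coincidence tests over all pairs; ordering tests per trajectory
length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import DAYS_PER_YEAR, Cohort

__all__ = [
    "jaccard_index",
    "coincidence_test",
    "ordering_test",
    "holm_adjust",
    "mine_trajectories",
    "OrderingTest",
    "Trajectory",
    "MiningResult",
]

logger = logging.getLogger(__name__)


def jaccard_index(carriers_a, carriers_b) -> float:
    """Jaccard coincidence |A∩B| / |A∪B| of two patient carrier sets."""
    a, b = set(carriers_a), set(carriers_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty carrier sets")
    return len(a & b) / len(union)


def _jaccard_from_counts(n_both: int, n_a: int, n_b: int) -> float:
    n_either = n_a + n_b - n_both
    return 0.0 if n_either == 0 else n_both / n_either


def _null_tail_counting(n, n_a, n_b, j_obs, n_boot, rng) -> float:
    """p = (1 + #{J* >= J_obs}) / (B + 1) under independent carriage at the
    observed marginals.

    Resampling two independent carriage vectors at rates n_a/n and n_b/n and
    intersecting them is distributionally identical to drawing the carrier
    counts from binomials and the overlap from a hypergeometric, which is what
    is sampled here (O(B) instead of O(B·n))."""
    na_star = rng.binomial(n, n_a / n, size=n_boot)
    nb_star = rng.binomial(n, n_b / n, size=n_boot)
    k_star = rng.hypergeometric(na_star, n - na_star, nb_star)
    denom = na_star + nb_star - k_star
    j_star = np.divide(k_star, denom, out=np.zeros(n_boot, float), where=denom > 0)
    return (1 + int((j_star >= j_obs - 1e-12).sum())) / (n_boot + 1)


def _null_tail_rb(n, n_a, n_b, j_obs, n_boot, rng) -> float:
    """Rao–Blackwellised version of the same null: marginal counts are
    resampled, but the overlap tail P(J* >= J_obs | n_a*, n_b*) is evaluated
    exactly from the hypergeometric survival function and averaged.  Yields a
    continuous p-value that can resolve far below 1/(B+1), which step-down
    adjustment over hundreds of pairs requires."""
    if j_obs <= 0:
        return 1.0
    na_star = rng.binomial(n, n_a / n, size=n_boot)
    nb_star = rng.binomial(n, n_b / n, size=n_boot)
    s = na_star + nb_star
    # J* >= j  <=>  k >= j*s/(1+j)  (J* is increasing in overlap k at fixed s)
    k_min = np.ceil(j_obs * s / (1.0 + j_obs) - 1e-9)
    tails = stats.hypergeom.sf(k_min - 1, n, na_star, nb_star)
    # tails are exact probabilities, so no add-one floor is needed; clip away 0
    return float(np.clip(tails.mean(), 1e-300, 1.0))


def coincidence_test(
    carriage_a,
    carriage_b,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "counting",
) -> float:
    """One-sided bootstrap p-value for the Jaccard coincidence of two blocks.

    The null resamples independent carriage vectors at the observed marginal
    prevalences; the p-value is the (add-one smoothed) fraction of resampled
    Jaccard values at least as large as the observed one.

    Parameters
    ----------
    carriage_a, carriage_b:
        Boolean carriage indicators over the same n patients.
    n_boot:
        Number of bootstrap resamples (>= 100).
    method:
        ``"counting"`` — count resampled exceedances (granularity 1/(B+1));
        ``"rb"`` — average exact hypergeometric overlap tails over resampled
        marginals (continuous, used inside the miner).
    """
    a = np.asarray(carriage_a, dtype=bool)
    b = np.asarray(carriage_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("carriage vectors must be 1-D and aligned")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 patients")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a in (0, n) or n_b in (0, n):
        warnings.warn("zero-variance carriage vector; coincidence p-value set to 1")
        return 1.0
    n_both = int((a & b).sum())
    j_obs = _jaccard_from_counts(n_both, n_a, n_b)
    rng = np.random.default_rng(seed)
    tail = {"counting": _null_tail_counting, "rb": _null_tail_rb}[method]
    return tail(n, n_a, n_b, j_obs, n_boot, rng)


@dataclass(frozen=True)
class OrderingTest:
    """Double one-tailed binomial test of which of two diagnoses comes first.

    Among patients carrying both diagnoses, ``n_a_first`` were diagnosed with
    A strictly earlier, ``n_b_first`` with B strictly earlier, and ``n_equal``
    on the same date.  Each one-tailed test counts the ties against the tested
    direction: ``p_a_first`` is P(X >= n_a_first) for X ~ Binomial(n, 1/2)
    with n the total count.
    """

    n_a_first: int
    n_b_first: int
    n_equal: int
    p_a_first: float
    p_b_first: float

    @property
    def n(self) -> int:
        return self.n_a_first + self.n_b_first + self.n_equal

    def direction(self, alpha: float = 0.05) -> str:
        """Significant direction at level *alpha* on the stored p-values."""
        if self.p_a_first < alpha:
            return "A->B"
        if self.p_b_first < alpha:
            return "B->A"
        return "none"


def ordering_test(n_a_first: int, n_b_first: int, n_equal: int = 0) -> OrderingTest:
    """Exact double one-tailed binomial ordering test (ties count against)."""
    if min(n_a_first, n_b_first, n_equal) < 0:
        raise ValueError("counts must be non-negative")
    n = n_a_first + n_b_first + n_equal
    if n < 1:
        raise ValueError("need at least one dual carrier")
    p_a = float(stats.binom.sf(n_a_first - 1, n, 0.5))
    p_b = float(stats.binom.sf(n_b_first - 1, n, 0.5))
    return OrderingTest(n_a_first, n_b_first, n_equal, p_a, p_b)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class Trajectory:
    """An ordered diagnosis sequence with its supporting statistics."""

    blocks: tuple[str, ...]
    support: int
    step_p_adjusted: tuple[float, ...]  # one Holm-adjusted p per consecutive step
    median_gaps_years: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.blocks)

    def __str__(self) -> str:
        return " -> ".join(self.blocks)


@dataclass
class MiningResult:
    """Pair statistics and the mined trajectories of one sex stratum."""

    pairs: pd.DataFrame
    trajectories: list[Trajectory]
    alpha: float
    min_support: int

    def trajectories_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trajectory": str(t),
                "length": len(t),
                "support": t.support,
                "max_step_p_adj": max(t.step_p_adjusted),
                "median_gaps_years": ";".join(f"{g:.3f}" for g in t.median_gaps_years),
            }
            for t in self.trajectories
        ]
        return pd.DataFrame(
            rows, columns=["trajectory", "length", "support", "max_step_p_adj", "median_gaps_years"]
        )


def _carriage_and_days(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Patient x block carriage (bool) and days-since-first (NaN where absent)."""
    ev = cohort.events
    days = ev.pivot_table(
        index="patient_id", columns="block_id", values="days_since_first", aggfunc="min"
    )
    carriage = days.notna().to_numpy()
    return carriage, days.to_numpy(), list(days.columns)


def _ordering_counts(days: np.ndarray, ia: int, ib: int, rows: np.ndarray) -> tuple[int, int, int]:
    da, db = days[rows, ia], days[rows, ib]
    return int((da < db).sum()), int((db < da).sum()), int((da == db).sum())


def _valid_orders(blocks: tuple[str, ...], edges: dict[tuple[str, str], float]) -> list[tuple[str, ...]]:
    """Total orders of *blocks* in which every consecutive pair is a significant
    edge and no significant edge points backwards."""
    out = []
    for perm in permutations(sorted(blocks)):
        pos = {b: i for i, b in enumerate(perm)}
        if any(pos[u] > pos[v] for (u, v) in edges):
            continue  # a significant ordering contradicts this arrangement
        if all((perm[i], perm[i + 1]) in edges for i in range(len(perm) - 1)):
            out.append(perm)
    return out


def mine_trajectories(
    cohort: Cohort,
    alpha: float = 0.05,
    min_support: int = 20,
    max_len: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
    multimorbid_only: bool = True,
) -> MiningResult:
    """Mine significant time-ordered diagnosis trajectories in one sex stratum.

    Stage 1 tests every block pair for coincidence (bootstrap Jaccard test,
    Holm over all pairs).  Stage 2 runs double one-tailed binomial ordering
    tests on the significantly coincident pairs (Holm over all length-2
    ordering p-values); directed pairs with support >= *min_support* become
    length-2 trajectories.  Stage 3 extends breadth-first: candidate
    (k+1)-sets are unions of two length-k trajectories sharing k-1 blocks; in
    the sub-population carrying all member blocks every pairwise ordering is
    re-tested (Holm per length), and a candidate is emitted when a total order
    exists whose consecutive pairs are all significant and which no
    significant ordering contradicts.  Only maximal trajectories (not an
    ordered subsequence of a longer one) are returned.

    The cohort should be single-sex and prevalence-filtered; by default only
    multimorbid patients (>= 2 blocks) enter the mining population.
    """
    if multimorbid_only:
        cohort = cohort.multimorbid()
    carriage, days, blocks = _carriage_and_days(cohort)
    n_patients = carriage.shape[0]
    root = np.random.SeedSequence(seed)
    rng_coin = np.random.default_rng(root.spawn(1)[0])

    # ---- stage 1: pairwise coincidence -------------------------------------
    both = carriage.T.astype(np.int64) @ carriage.astype(np.int64)
    n_carr = carriage.sum(axis=0)
    idx_pairs = list(combinations(range(len(blocks)), 2))
    rows = []
    for ia, ib in idx_pairs:
        n_a, n_b, n_both = int(n_carr[ia]), int(n_carr[ib]), int(both[ia, ib])
        j = _jaccard_from_counts(n_both, n_a, n_b)
        if n_a in (0, n_patients) or n_b in (0, n_patients):
            p = 1.0
        else:
            p = _null_tail_rb(n_patients, n_a, n_b, j, n_boot, rng_coin)
        rows.append(
            {
                "block_a": blocks[ia],
                "block_b": blocks[ib],
                "n_both": n_both,
                "n_either": n_a + n_b - n_both,
                "jaccard": j,
                "p_coincidence": p,
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["block_a", "block_b", "n_both", "n_either", "jaccard", "p_coincidence"],
    )
    if pairs.empty:
        return MiningResult(pairs, [], alpha, min_support)
    pairs["p_coincidence_adj"] = holm_adjust(pairs["p_coincidence"])
    pairs["coincident"] = pairs["p_coincidence_adj"] < alpha

    # ---- stage 2: ordering of coincident pairs -----------------------------
    block_idx = {b: i for i, b in enumerate(blocks)}
    sig = pairs[pairs["coincident"] & (pairs["n_both"] >= min_support)]
    tests, raw_ps = [], []
    for row in sig.itertuples(index=False):
        ia, ib = block_idx[row.block_a], block_idx[row.block_b]
        dual = carriage[:, ia] & carriage[:, ib]
        t = ordering_test(*_ordering_counts(days, ia, ib, dual))
        tests.append((row.block_a, row.block_b, t))
        raw_ps.extend([t.p_a_first, t.p_b_first])
    adj = holm_adjust(raw_ps) if raw_ps else np.array([])

    ord_rows = []
    edges_l2: dict[tuple[str, str], float] = {}
    for i, (a, b, t) in enumerate(tests):
        pa_adj, pb_adj = adj[2 * i], adj[2 * i + 1]
        if pa_adj < alpha:
            direction = "A->B"
            edges_l2[(a, b)] = pa_adj
        elif pb_adj < alpha:
            direction = "B->A"
            edges_l2[(b, a)] = pb_adj
        else:
            direction = "none"
        ord_rows.append(
            {
                "block_a": a,
                "block_b": b,
                "n_a_first": t.n_a_first,
                "n_b_first": t.n_b_first,
                "n_equal": t.n_equal,
                "p_a_first": t.p_a_first,
                "p_b_first": t.p_b_first,
                "p_a_first_adj": pa_adj,
                "p_b_first_adj": pb_adj,
                "direction": direction,
            }
        )
    ordering = pd.DataFrame(
        ord_rows,
        columns=[
            "block_a", "block_b", "n_a_first", "n_b_first", "n_equal",
            "p_a_first", "p_b_first", "p_a_first_adj", "p_b_first_adj", "direction",
        ],
    )
    pairs = pairs.merge(ordering, on=["block_a", "block_b"], how="left")

    def _support_rows(blks: tuple[str, ...]) -> np.ndarray:
        mask = np.ones(n_patients, dtype=bool)
        for b in blks:
            mask &= carriage[:, block_idx[b]]
        return mask

    def _median_gaps(order: tuple[str, ...], rows_mask: np.ndarray) -> tuple[float, ...]:
        gaps = []
        for u, v in zip(order, order[1:]):
            du = days[rows_mask, block_idx[u]]
            dv = days[rows_mask, block_idx[v]]
            gaps.append(float(np.median(dv - du)) / DAYS_PER_YEAR)
        return tuple(gaps)

    trajectories: list[Trajectory] = []
    frontier: list[tuple[tuple[str, ...], dict[tuple[str, str], float]]] = []
    for (a, b), p_adj in sorted(edges_l2.items()):
        order = (a, b)
        rows_mask = _support_rows(order)
        trajectories.append(
            Trajectory(order, int(rows_mask.sum()), (float(p_adj),), _median_gaps(order, rows_mask))
        )
        frontier.append((order, {(a, b): p_adj}))

    # ---- stage 3: breadth-first extension ----------------------------------
    length = 2
    while frontier and length < max_len:
        cand_sets: set[tuple[str, ...]] = set()
        for (t1, _), (t2, _) in combinations(frontier, 2):
            shared = set(t1) & set(t2)
            if len(shared) == length - 1:
                cand_sets.add(tuple(sorted(set(t1) | set(t2))))
        # test every pairwise ordering within each candidate sub-population
        cand_tests: list[tuple[tuple[str, ...], str, str, OrderingTest]] = []
        raw_ps = []
        supports: dict[tuple[str, ...], np.ndarray] = {}
        for cand in sorted(cand_sets):
            rows_mask = _support_rows(cand)
            if int(rows_mask.sum()) < min_support:
                continue
            supports[cand] = rows_mask
            for a, b in combinations(cand, 2):
                t = ordering_test(
                    *_ordering_counts(days, block_idx[a], block_idx[b], rows_mask)
                )
                cand_tests.append((cand, a, b, t))
                raw_ps.extend([t.p_a_first, t.p_b_first])
        adj = holm_adjust(raw_ps) if raw_ps else np.array([])
        cand_edges: dict[tuple[str, ...], dict[tuple[str, str], float]] = {
            c: {} for c in supports
        }
        for i, (cand, a, b, t) in enumerate(cand_tests):
            pa_adj, pb_adj = adj[2 * i], adj[2 * i + 1]
            if pa_adj < alpha:
                cand_edges[cand][(a, b)] = pa_adj
            elif pb_adj < alpha:
                cand_edges[cand][(b, a)] = pb_adj
        new_frontier = []
        for cand, edges in sorted(cand_edges.items()):
            for order in _valid_orders(cand, edges):
                rows_mask = supports[cand]
                step_p = tuple(edges[(order[i], order[i + 1])] for i in range(len(order) - 1))
                new_frontier.append((order, edges))
                trajectories.append(
                    Trajectory(order, int(rows_mask.sum()), step_p, _median_gaps(order, rows_mask))
                )
        frontier = new_frontier
        length += 1

    trajectories = _maximal_only(trajectories)
    return MiningResult(pairs, trajectories, alpha, min_support)


def _is_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    it = iter(long)
    return all(b in it for b in short)


def _maximal_only(trajectories: list[Trajectory]) -> list[Trajectory]:
    keep = []
    for t in trajectories:
        if not any(
            len(o) > len(t) and _is_subsequence(t.blocks, o.blocks)
            for o in trajectories
        ):
            keep.append(t)
    return sorted(keep, key=lambda t: (-len(t), t.blocks))
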