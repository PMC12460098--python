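"""Permutational ANOVA on avoidance-distance tables.

Distance-based sums of squares are partitioned over the terms of a crossed
factorial design (up to three factors, fixed or random) via projections of
the Gower-centred squared-distance matrix onto orthogonal contrast
subspaces.  Pseudo-F ratios use denominators chosen by expected-mean-squares
rules for crossed mixed models: a fixed term crossed with a random factor is
tested against that interaction's mean square, everything else against the
residual.  Null distributions come from permutation of reduced-model
residuals (Freedman–Lane: residuals of the model excluding the tested term
are permuted and added back to the reduced-model fit), with the observed
statistic included in both numerator and denominator of the p-value.  A
parametric tail probability from the F reference distribution (``p_MC``) is
always reported for use when few unique permutations exist; with Euclidean
distances on the univariate responses in scope it is exact under Gaussian
errors, not a moment-matched approximation.

Because the response is a single numeric column compared by Euclidean
distance, the distance-based partition coincides with the classical ANOVA
partition; the permutation engine exploits this algebraic identity and works
on response vectors, while observed sums of squares are computed from the
Gower-centred matrix.  The identity itself is a tested invariant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDesignError, DegenerateTestError

__all__ = [
    "Factor",
    "Design",
    "PermanovaResult",
    "PairwiseResult",
    "total_ss",
    "partition",
    "permanova",
    "count_unique_permutations",
    "pmc_value",
    "pool_terms",
    "pairwise",
]

_REL_TOL = 1e-9  # tie tolerance when comparing permuted F to the observed F


@dataclass(frozen=True)
class Factor:
    name: str
    role: str = "fixed"

    def __post_init__(self):
        if self.role not in ("fixed", "random"):
            raise ValueError(f"factor role must be fixed|random, got {self.role!r}")


@dataclass(frozen=True)
class Design:
    """A crossed factorial design on one numeric response column.

    ``terms`` are tuples of factor names (main effects and interactions);
    their order is kept in the output.  Only the Euclidean distance is
    supported — it is the metric under which the distance-based partition
    equals the classical univariate one.
    """

    factors: tuple[Factor, ...]
    terms: tuple[tuple[str, ...], ...]
    response: str = "distance_m"
    distance: str = "euclidean"

    def __post_init__(self):
        factors = tuple(self.factors)
        if not 1 <= len(factors) <= 3:
            raise ValueError("between 1 and 3 factors are supported")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        terms = tuple(tuple(t) for t in self.terms)
        for t in terms:
            if not t or any(n not in names for n in t) or len(set(t)) != len(t):
                raise ValueError(f"invalid term {t!r}")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean distance is supported")
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "terms", terms)

    @classmethod
    def full_factorial(cls, factors: Sequence[Factor], response: str = "distance_m") -> "Design":
        names = [f.name for f in factors]
        terms = []
        for order in range(1, len(names) + 1):
            terms.extend(itertools.combinations(names, order))
        return cls(factors=tuple(factors), terms=tuple(terms), response=response)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def random_factors(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.role == "random")

    def term_label(self, term: tuple[str, ...]) -> str:
        return ":".join(term)


@dataclass
class PermanovaResult:
    """Per-term partition and tests plus residual bookkeeping."""

    table: pd.DataFrame  # term, df, ss, ms, F, denominator, p_perm, p_MC, n_unique
    residual_df: int
    residual_ss: float
    residual_ms: float
    total_ss: float
    n_perm: int
    seed: int | None
    method: str
    pooling_log: list = field(default_factory=list)

    def p_use(self, term_label: str, min_unique: int = 100) -> float:
        """p_perm, or p_MC when fewer than ``min_unique`` unique permutations
        exist (the reporting rule used throughout the pipeline)."""
        row = self.table.loc[self.table["term"] == term_label].iloc[0]
        return float(row["p_MC"] if row["n_unique"] < min_unique else row["p_perm"])


@dataclass
class PairwiseResult:
    """Two-group follow-up tests for each level pair of one factor."""

    table: pd.DataFrame  # level_a, level_b, t, F, p_perm, p_MC, n_unique
    factor: str
    n_perm: int
    seed: int | None


# ---------------------------------------------------------------------------
# Distance-matrix machinery
# ---------------------------------------------------------------------------


def gower_centred(D: np.ndarray) -> np.ndarray:
    """Gower-centred matrix G = -(1/2) J D^2 J with J = I - 11'/n."""
    D = np.asarray(D, float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def total_ss(D: np.ndarray, n: int | None = None) -> float:
    """Total sum of squares of a distance matrix: (1/n) sum_{i<j} d_ij^2.

    For Euclidean distances on a univariate response this equals
    ``sum((y - mean(y))^2)``.
    """
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must be symmetric with zero diagonal")
    n = n if n is not None else D.shape[0]
    return float(np.sum(np.triu(D, 1) ** 2) / n)


def _euclidean_D(y: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(y, float)[:, None], metric="euclidean"))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _helmert(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) contrast basis orthogonal to the constant."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -float(j)
        H[:, j - 1] /= math.sqrt(j * (j + 1))
    return H


class _ModelMatrices:
    """Contrast columns per term, cached projections, df bookkeeping."""

    def __init__(self, table: pd.DataFrame, design: Design):
        self.design = design
        self.n = len(table)
        if self.n < 2:
            raise DegenerateDesignError("need at least two observations")
        self.codes: dict[str, np.ndarray] = {}
        self.n_levels: dict[str, int] = {}
        self.bases: dict[str, np.ndarray] = {}
        for f in design.factors:
            if f.name not in table.columns:
                raise ValueError(f"factor column {f.name!r} missing from table")
            levels, codes = np.unique(np.asarray(table[f.name]), return_inverse=True)
            if len(levels) < 2:
                raise DegenerateDesignError(f"factor {f.name!r} has a single level")
            self.codes[f.name] = codes
            self.n_levels[f.name] = len(levels)
            self.bases[f.name] = _helmert(len(levels))

        self.blocks: dict[tuple[str, ...], np.ndarray] = {}
        for term in design.terms:
            self._check_cells(table, term)
            cols = np.ones((self.n, 1))
            for name in term:
                contr = self.bases[name][self.codes[name]]  # (n, k-1)
                cols = (cols[:, :, None] * contr[:, None, :]).reshape(self.n, -1)
            self.blocks[term] = cols

        self.X_full = np.hstack(
            [np.ones((self.n, 1))] + [self.blocks[t] for t in design.terms]
        )
        self.rank_full = np.linalg.matrix_rank(self.X_full)
        self.residual_df = self.n - self.rank_full
        self._proj_cache: dict[frozenset, np.ndarray] = {}

    def _check_cells(self, table: pd.DataFrame, term: tuple[str, ...]) -> None:
        sizes = table.groupby([*term], observed=True).size()
        expected = int(np.prod([self.n_levels[f] for f in term]))
        if len(sizes) < expected:
            raise DegenerateDesignError(
                f"term {':'.join(term)} has empty cells ({len(sizes)}/{expected} filled)"
            )

    def df(self, term: tuple[str, ...]) -> int:
        return int(np.prod([self.n_levels[f] - 1 for f in term]))

    def projection(self, include: Sequence[tuple[str, ...]]) -> np.ndarray:
        """Hat matrix of intercept + the given terms' contrast columns."""
        key = frozenset(include)
        if key not in self._proj_cache:
            X = np.hstack([np.ones((self.n, 1))] + [self.blocks[t] for t in include])
            Q, _ = np.linalg.qr(X)
            # drop numerically null columns from rank-deficient layouts
            keep = np.abs(np.diag(np.linalg.qr(X, mode="r"))) > 1e-10
            if not keep.all():
                Q = Q[:, keep]
            self._proj_cache[key] = Q @ Q.T
        return self._proj_cache[key]


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------


def partition(table: pd.DataFrame, design: Design) -> PermanovaResult:
    """Sums of squares and degrees of freedom per term, plus residual.

    Observed SS are computed from the Gower-centred Euclidean distance
    matrix: each term's SS is the drop in residual SS when its contrast
    columns join the model (for balanced layouts this is the usual
    orthogonal decomposition, and term SS plus residual SS add to the
    total).
    """
    mm = _ModelMatrices(table, design)
    y = np.asarray(table[design.response], float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    G = gower_centred(_euclidean_D(y))
    ss_tot = float(np.trace(G))

    def rss(P: np.ndarray) -> float:
        M = np.eye(mm.n) - P
        return float(np.trace(M @ G @ M))

    P_full = mm.projection(design.terms)
    rss_full = rss(P_full)
    rows = []
    for term in design.terms:
        others = [t for t in design.terms if t != term]
        ss = rss(mm.projection(others)) - rss_full
        dfree = mm.df(term)
        rows.append(
            dict(term=design.term_label(term), df=dfree, ss=max(ss, 0.0),
                 ms=max(ss, 0.0) / dfree)
        )
    tableout = pd.DataFrame(rows, columns=["term", "df", "ss", "ms"])
    res_df = mm.residual_df
    return PermanovaResult(
        table=tableout,
        residual_df=res_df,
        residual_ss=rss_full,
        residual_ms=rss_full / res_df if res_df > 0 else float("nan"),
        total_ss=ss_tot,
        n_perm=0,
        seed=None,
        method="partition",
    )


# ---------------------------------------------------------------------------
# Expected-mean-squares denominators
# ---------------------------------------------------------------------------


def _denominator_term(
    term: tuple[str, ...], design: Design
) -> tuple[str, ...] | None:
    """EMS denominator for ``term``: the interaction with a random factor not
    already in the term (if fitted), else the residual (None)."""
    candidates = []
    for r in design.random_factors:
        if r in term:
            continue
        target = set(term) | {r}
        for t in design.terms:
            if set(t) == target:
                candidates.append(t)
    if not candidates:
        return None
    if len(candidates) > 1:
        raise DegenerateTestError(
            f"no exact EMS test for term {':'.join(term)} (multiple random interactions)"
        )
    return candidates[0]


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def count_unique_permutations(
    design: Design, term: tuple[str, ...] | str, table: pd.DataFrame
) -> int:
    """Number of distinct assignments of observations to the term's cells:
    the multinomial coefficient n! / prod(cell size!)."""
    if isinstance(term, str):
        term = tuple(term.split(":"))
    for name in term:
        if name not in table.columns:
            raise ValueError(f"factor column {name!r} missing")
    sizes = table.groupby(list(term), observed=True).size().to_numpy()
    out = math.factorial(int(sizes.sum()))
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def pmc_value(F_observed: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) reference distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("df1 and df2 must be >= 1")
    return float(sps.f.sf(F_observed, df1, df2))


def _distinct_assignments(codes: np.ndarray, limit: int = 200_000) -> np.ndarray:
    """All distinct permutations of a small label vector, as an array."""
    n = len(codes)
    seen = sorted(set(itertools.permutations(codes.tolist())))
    if len(seen) > limit:
        raise DegenerateTestError("too many unique permutations to enumerate")
    return np.asarray(seen, dtype=codes.dtype)


def permanova(
    table: pd.DataFrame,
    design: Design,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "residual",
) -> PermanovaResult:
    """Permutational ANOVA of the design on the response column.

    ``method="residual"`` permutes reduced-model residuals (Freedman–Lane)
    ``n_perm`` times per term; ``method="exact"`` enumerates every distinct
    assignment (single-factor designs only) and reports the exact
    permutation p-value without the +1 convention, since the observed
    assignment is part of the enumeration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("residual", "exact"):
        raise ValueError(f"unknown method {method!r}")

    base = partition(table, design)
    mm = _ModelMatrices(table, design)
    y = np.asarray(table[design.response], float)
    n = mm.n
    P_full = mm.projection(design.terms)
    M_full = np.eye(n) - P_full

    ss = dict(zip(base.table["term"], base.table["ss"]))
    dfs = dict(zip(base.table["term"], base.table["df"]))

    # observed F per term
    obs: dict[str, tuple[float, int, tuple[str, ...] | None]] = {}
    for term in design.terms:
        lbl = design.term_label(term)
        den = _denominator_term(term, design)
        if den is None:
            if base.residual_df < 1:
                raise DegenerateTestError("no residual degrees of freedom")
            ms_den, df_den = base.residual_ms, base.residual_df
        else:
            dl = design.term_label(den)
            ms_den, df_den = ss[dl] / dfs[dl], dfs[dl]
        if ms_den == 0:
            raise DegenerateTestError(f"zero denominator mean square for {lbl}")
        obs[lbl] = (ss[lbl] / dfs[lbl] / ms_den, df_den, den)

    rng = np.random.default_rng(seed)
    rows = []
    if method == "exact":
        if len(design.terms) != 1 or len(design.terms[0]) != 1:
            raise DegenerateTestError("exact enumeration supports one-factor designs only")
        term = design.terms[0]
        lbl = design.term_label(term)
        codes = mm.codes[term[0]]
        perms = _distinct_assignments(codes)
        F_obs = obs[lbl][0]
        Fs = _one_factor_F(y, perms, mm.n_levels[term[0]])
        p_perm = float(np.mean(Fs >= F_obs * (1 - _REL_TOL)))
        rows.append(
            dict(
                term=lbl,
                df=dfs[lbl],
                ss=ss[lbl],
                ms=ss[lbl] / dfs[lbl],
                F=F_obs,
                denominator="residual",
                p_perm=p_perm,
                p_MC=pmc_value(F_obs, dfs[lbl], obs[lbl][1]),
                n_unique=len(perms),
            )
        )
        n_perm_out = len(perms)
    else:
        for term in design.terms:
            lbl = design.term_label(term)
            F_obs, df_den, den = obs[lbl]
            others = [t for t in design.terms if t != term]
            P_red = mm.projection(others)
            fitted = P_red @ y
            resid = y - fitted
            idx = np.argsort(rng.random((n_perm, n)), axis=1)
            Y = fitted[None, :] + resid[idx]  # (n_perm, n)

            P_wo_term = mm.projection(others)
            ss_term = _rss_rows(Y, P_wo_term) - _rss_rows(Y, P_full)
            if den is None:
                ms_den_perm = _rss_rows(Y, P_full) / base.residual_df
            else:
                others_den = [t for t in design.terms if t != den]
                ss_den = _rss_rows(Y, mm.projection(others_den)) - _rss_rows(Y, P_full)
                ms_den_perm = ss_den / dfs[design.term_label(den)]
            with np.errstate(divide="ignore", invalid="ignore"):
                F_perm = (ss_term / dfs[lbl]) / ms_den_perm
            F_perm = np.where(np.isfinite(F_perm), F_perm, np.inf)
            p_perm = (np.sum(F_perm >= F_obs * (1 - _REL_TOL)) + 1) / (n_perm + 1)
            rows.append(
                dict(
                    term=lbl,
                    df=dfs[lbl],
                    ss=ss[lbl],
                    ms=ss[lbl] / dfs[lbl],
                    F=F_obs,
                    denominator="residual" if den is None else design.term_label(den),
                    p_perm=float(p_perm),
                    p_MC=pmc_value(F_obs, dfs[lbl], df_den),
                    n_unique=count_unique_permutations(design, term, table),
                )
            )
        n_perm_out = n_perm

    return PermanovaResult(
        table=pd.DataFrame(
            rows,
            columns=["term", "df", "ss", "ms", "F", "denominator", "p_perm", "p_MC", "n_unique"],
        ),
        residual_df=base.residual_df,
        residual_ss=base.residual_ss,
        residual_ms=base.residual_ms,
        total_ss=base.total_ss,
        n_perm=n_perm_out,
        seed=seed,
        method=method,
    )


def _rss_rows(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Row-wise residual sum of squares of Y (n_perm, n) under hat matrix P."""
    R = Y - Y @ P
    return np.einsum("ij,ij->i", R, R)


def _one_factor_F(y: np.ndarray, assignments: np.ndarray, k: int) -> np.ndarray:
    """Classical one-way F for each row of group assignments (vectorised)."""
    n = y.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    Fs = np.empty(len(assignments))
    counts = np.array([np.sum(assignments[0] == g) for g in range(k)], dtype=float)
    for i, a in enumerate(assignments):
        sums = np.bincount(a, weights=y, minlength=k)
        ss_b = float(np.sum(sums**2 / counts)) - n * y.mean() ** 2
        ss_w = ss_tot - ss_b
        df_b, df_w = k - 1, n - k
        Fs[i] = (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.inf
    return Fs


# ---------------------------------------------------------------------------
# Pooling and pairwise follow-ups
# ---------------------------------------------------------------------------


def pool_terms(
    result: PermanovaResult,
    table: pd.DataFrame,
    design: Design,
    threshold: float = 0.25,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[PermanovaResult, Design]:
    """Iteratively pool non-significant terms into the residual.

    Starting from the highest-order terms, any term with ``p_perm`` at or
    above the threshold (and not marginal to a retained higher-order term)
    is dropped and the model refitted, so its SS and df merge into the
    residual.  Returns the final result (carrying a pooling log) and the
    pooled design.
    """
    n_perm = n_perm if n_perm is not None else result.n_perm or 999
    terms = list(design.terms)
    res = result
    log: list[dict] = list(result.pooling_log)
    while True:
        p = dict(zip(res.table["term"], res.table["p_perm"]))
        candidates = []
        for t in terms:
            lbl = ":".join(t)
            if p.get(lbl, 0.0) < threshold:
                continue
            if any(set(t) < set(t2) for t2 in terms if t2 != t):
                continue  # keep terms marginal to retained interactions
            candidates.append(t)
        if not candidates:
            res.pooling_log = log
            return res, replace(design, terms=tuple(terms))
        candidates.sort(key=lambda t: (-len(t), -p[":".join(t)]))
        drop = candidates[0]
        row = res.table.loc[res.table["term"] == ":".join(drop)].iloc[0]
        log.append(
            dict(term=":".join(drop), p_perm=float(row["p_perm"]),
                 df=int(row["df"]), ss=float(row["ss"]))
        )
        terms.remove(drop)
        if not terms:
            raise DegenerateDesignError("pooling removed every term from the model")
        res = permanova(table, replace(design, terms=tuple(terms)), n_perm=n_perm, seed=seed)


def pairwise(
    table: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int | None = None,
    stratum: Mapping[str, object] | None = None,
    design: Design | None = None,
    method: str = "residual",
) -> PairwiseResult:
    """Two-group permutation tests for every level pair of ``factor``.

    ``stratum`` restricts the table to fixed values of other columns before
    testing (e.g. one treatment level).  Each pair is a two-group
    permutational ANOVA on the same seed, so the single pair of a two-level
    factor reproduces the omnibus test exactly; ``t = sqrt(F)``.
    """
    sub = table
    if stratum:
        for k, v in stratum.items():
            sub = sub[sub[k] == v]
    response = design.response if design is not None else "distance_m"
    levels = list(pd.unique(sub[factor]))
    if len(levels) < 2:
        raise DegenerateTestError(f"factor {factor!r} needs >= 2 levels in the stratum")
    rows = []
    for a, b in itertools.combinations(levels, 2):
        pair = sub[sub[factor].isin([a, b])]
        sizes = pair.groupby(factor, observed=True).size()
        if (sizes < 2).any():
            raise DegenerateTestError(
                f"levels {a!r}/{b!r} need >= 2 observations each"
            )
        d = Design(factors=(Factor(factor, "fixed"),), terms=((factor,),), response=response)
        if pair[response].nunique() == 1:
            # identical groups: no variation, define t = 0, p = 1
            rows.append(dict(level_a=a, level_b=b, t=0.0, F=0.0, p_perm=1.0,
                             p_MC=1.0, n_unique=count_unique_permutations(d, (factor,), pair)))
            continue
        res = permanova(pair, d, n_perm=n_perm, seed=seed, method=method)
        r = res.table.iloc[0]
        rows.append(
            dict(
                level_a=a,
                level_b=b,
                t=float(np.sqrt(max(r["F"], 0.0))),
                F=float(r["F"]),
                p_perm=float(r["p_perm"]),
                p_MC=float(r["p_MC"]),
                n_unique=int(r["n_unique"]),
            )
        )
    return PairwiseResult(
        table=pd.DataFrame(rows, columns=["level_a", "level_b", "t", "F", "p_perm", "p_MC", "n_unique"]),
        factor=factor,
        n_perm=n_perm,
        seed=seed,
    )
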