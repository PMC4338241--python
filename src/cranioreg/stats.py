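"""Permutation-based statistics for the superimposition study.

The study design is a balanced crossed layout — technique (fixed) x
operator (random) x session/time (fixed), with patients as replicates — and
the inference layer mirrors the distance-based permutational MANOVA
tradition: sums of squares are partitioned from a (transformed) response
distance matrix, pseudo-F statistics use expected-mean-square denominators
appropriate for the mixed model, and p-values come from unrestricted
permutation of the raw data (with a moment-matched Monte Carlo
approximation when few unique permutations exist). Dispersion homogeneity
(distances to group spatial medians) and Bland-Altman agreement summaries
complete the layer.

The model classes follow the fit/results convention: build a model from a
DataFrame, call ``fit()``, inspect the results object or ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "UnbalancedDesignError",
    "Permanova",
    "PermanovaResults",
    "permanova",
    "pairwise_posthoc",
    "permdisp",
    "bland_altman",
    "AgreementSummary",
    "LOG10_FLOOR_MM",
]

# deviations from duplicate controls can be ~0; floor before log10
LOG10_FLOOR_MM = 1e-4


class UnbalancedDesignError(ValueError):
    """Only balanced crossed designs are supported."""


def _log10_floor(x, eps: float = LOG10_FLOOR_MM) -> np.ndarray:
    return np.log10(np.maximum(np.asarray(x, float), eps))


_TRANSFORMS = {
    "log10": _log10_floor,
    "fourth_root": lambda x: np.power(np.maximum(np.asarray(x, float), 0.0), 0.25),
    "none": lambda x: np.asarray(x, float),
}


def _gower_scores(dm: np.ndarray):
    """Factor a squared-distance Gower matrix into signed score vectors.

    Returns (scores, signs) such that the distance-based SS of any projection
    equals sum_k sign_k * ||proj(scores_k)||^2. For Euclidean distances all
    signs are +1; semimetric options (Bray-Curtis) can carry negative
    eigenvalues.
    """
    n = dm.shape[0]
    A = -0.5 * dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh((G + G.T) / 2)
    keep = np.abs(w) > 1e-10 * max(np.abs(w).max(), 1.0)
    w, V = w[keep], V[:, keep]
    scores = V * np.sqrt(np.abs(w))
    return scores, np.sign(w)


@dataclass
class PermanovaResults:
    """Source table and permutation metadata of a fitted PERMANOVA."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    transform: str
    distance: str

    def summary(self) -> str:
        lines = [
            "Permutational MANOVA "
            f"({self.distance} distance, {self.transform} transform, "
            f"{self.n_permutations} permutations)",
            "-" * 78,
        ]
        with pd.option_context("display.float_format", "{:0.4f}".format):
            lines.append(self.table.to_string())
        return "\n".join(lines)

    def p_value(self, source: str, kind: str = "perm") -> float:
        row = self.table.loc[self.table["source"] == source]
        if row.empty:
            raise KeyError(f"no source named {source!r}")
        return float(row.iloc[0]["p_perm" if kind == "perm" else "p_montecarlo"])


class Permanova:
    """Distance-based permutational MANOVA for balanced crossed designs.

    Parameters
    ----------
    data : DataFrame with one row per observation.
    response : column name (or list of names) holding the response(s).
    factors : crossed design factors, e.g. ``["technique", "operator", "time"]``.
    random_factors : names treated as random; fixed-effect pseudo-F then uses
        the interaction with the random factor as its denominator (classical
        expected-mean-square rules).
    transform : ``log10`` (default, floored at 1e-4), ``fourth_root`` or ``none``.
    distance : ``euclidean`` (default) or ``braycurtis``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response,
        factors,
        random_factors=(),
        transform: str = "log10",
        distance: str = "euclidean",
    ):
        self.data = data.reset_index(drop=True)
        self.response = [response] if isinstance(response, str) else list(response)
        self.factors = list(factors)
        self.random_factors = set(random_factors)
        if not self.random_factors <= set(self.factors):
            raise ValueError("random_factors must be a subset of factors")
        self.transform = transform
        self.distance = distance
        self._validate_balance()

    def _validate_balance(self):
        counts = self.data.groupby(self.factors, observed=True).size()
        if counts.nunique() != 1:
            raise UnbalancedDesignError(
                "unbalanced design: cell sizes "
                f"{sorted(counts.unique())}; only balanced crossings are supported"
            )
        self.n_replicates = int(counts.iloc[0])

    # -- design construction ------------------------------------------
    def _effect_bases(self):
        """Orthonormal basis (QR) per effect; orthogonal across effects for
        balanced designs (Helmert contrast codes)."""
        n = len(self.data)
        codes = {}
        for f in self.factors:
            levels, idx = np.unique(self.data[f].to_numpy(), return_inverse=True)
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} needs >= 2 levels")
            K = helmert(len(levels)).T  # (a, a-1), columns orthonormal, ⟂ 1
            codes[f] = K[idx]
        effects = []
        for k in range(1, len(self.factors) + 1):
            for combo in itertools.combinations(self.factors, k):
                cols = None
                for f in combo:
                    cols = codes[f] if cols is None else (
                        cols[:, :, None] * codes[f][:, None, :]
                    ).reshape(n, -1)
                Q, _ = np.linalg.qr(cols)
                effects.append((" x ".join(combo), frozenset(combo), Q))
        return effects

    def _denominator(self, effect_set, effect_sets):
        """Expected-MS denominator: fixed-only effects test against their
        interaction with the random factor(s); effects already containing all
        random factors test against the residual."""
        missing = self.random_factors - effect_set
        if missing:
            cand = frozenset(effect_set | self.random_factors)
            if cand in effect_sets and cand != effect_set:
                return cand
        return None  # residual

    # -- fitting -------------------------------------------------------
    def fit(self, n_permutations: int | str = 9999, seed: int | None = 0):
        data = self.data
        n = len(data)
        y = _TRANSFORMS[self.transform](data[self.response].to_numpy())
        if self.distance == "euclidean":
            scores = y - y.mean(axis=0, keepdims=True)
            signs = np.ones(scores.shape[1])
        else:
            dm = squareform(pdist(y, metric=self.distance))
            scores, signs = _gower_scores(dm)

        effects = self._effect_bases()
        effect_sets = {s for _, s, _ in effects}
        ss_total = float(np.sum(signs * np.sum(scores**2, axis=0)))
        df_total = n - 1

        def all_ss(sc):
            return np.array(
                [float(np.sum(signs * np.sum((Q.T @ sc) ** 2, axis=0))) for _, _, Q in effects]
            )

        ss_obs = all_ss(scores)
        df = np.array(
            [
                int(np.prod([data[f].nunique() - 1 for f in combo]))
                for _, combo, _ in [(nm, list(s), Q) for nm, s, Q in effects]
            ]
        )
        ss_res = ss_total - ss_obs.sum()
        df_res = df_total - int(df.sum())
        if df_res <= 0:
            raise UnbalancedDesignError("no residual degrees of freedom (need replicates)")

        degenerate = ss_total <= 1e-12

        def f_stats(ss_vec, ss_resid):
            ms = ss_vec / df
            ms_res = ss_resid / df_res
            out = np.empty(len(effects))
            for i, (_, s, _) in enumerate(effects):
                den_set = self._denominator(s, effect_sets)
                if den_set is None:
                    den = ms_res
                else:
                    j = next(k for k, (_, s2, _) in enumerate(effects) if s2 == den_set)
                    den = ms[j]
                out[i] = ms[i] / den if den > 0 else np.nan
            return out, ms, ms_res

        if degenerate:
            f_obs = np.full(len(effects), np.nan)
            ms_obs = np.zeros(len(effects))
            ms_res = 0.0
        else:
            f_obs, ms_obs, ms_res = f_stats(ss_obs, ss_res)

        # permutation distribution (unrestricted permutation of raw data)
        exhaustive = n_permutations == "exhaustive"
        if exhaustive:
            if math.factorial(n) > 50000:
                raise ValueError("exhaustive enumeration infeasible for n > 8")
            perms = list(itertools.permutations(range(n)))[1:]
        else:
            rng = np.random.default_rng(None if seed is None else int(seed) % (2**31))
            perms = [rng.permutation(n) for _ in range(int(n_permutations))]

        n_perm = len(perms)
        if not degenerate and n_perm:
            # vectorised: project all permuted score matrices at once
            perm_idx = np.asarray(perms, dtype=int)  # (P, n)
            Q_all = np.concatenate([Q for _, _, Q in effects], axis=1)
            slices = []
            start = 0
            for _, _, Q in effects:
                slices.append(slice(start, start + Q.shape[1]))
                start += Q.shape[1]
            # (P, n, r) gathered scores -> (P, cols, r) projections
            proj = np.einsum("pnr,nc->pcr", scores[perm_idx], Q_all, optimize=True)
            sq = np.einsum("pcr,r->pc", proj**2, signs)
            ss_perm = np.stack([sq[:, sl].sum(axis=1) for sl in slices], axis=1)
            ms_perm = ss_perm / df
            ms_res_perm = (ss_total - ss_perm.sum(axis=1)) / df_res
            f_perm_all = np.empty((n_perm, len(effects)))
            for i, (_, s, _) in enumerate(effects):
                den_set = self._denominator(s, effect_sets)
                if den_set is None:
                    den = ms_res_perm
                else:
                    j = next(k for k, (_, s2, _) in enumerate(effects) if s2 == den_set)
                    den = ms_perm[:, j]
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_perm_all[:, i] = np.where(den > 0, ms_perm[:, i] / den, np.nan)
            count_ge = 1 + np.nansum(f_perm_all >= f_obs - 1e-12, axis=0)
            p_perm = count_ge / (n_perm + 1)
            p_mc = np.array(
                [_pearson3_tail(f_perm_all[:, i], f_obs[i]) for i in range(len(effects))]
            )
        else:
            p_perm = np.full(len(effects), np.nan)
            p_mc = np.full(len(effects), np.nan)

        unique_perms = min(math.factorial(n), 10**9)
        rows = []
        for i, (name, _, _) in enumerate(effects):
            rows.append(
                dict(
                    source=name,
                    df=int(df[i]),
                    SS=ss_obs[i],
                    MS=ms_obs[i],
                    pseudo_F=f_obs[i],
                    p_perm=p_perm[i],
                    p_montecarlo=p_mc[i],
                )
            )
        rows.append(
            dict(
                source="Residual", df=df_res, SS=ss_res, MS=ms_res,
                pseudo_F=np.nan, p_perm=np.nan, p_montecarlo=np.nan,
            )
        )
        rows.append(
            dict(
                source="Total", df=df_total, SS=ss_total, MS=np.nan,
                pseudo_F=np.nan, p_perm=np.nan, p_montecarlo=np.nan,
            )
        )
        table = pd.DataFrame(rows)
        res = PermanovaResults(
            table=table,
            n_permutations=n_perm,
            seed=None if exhaustive else seed,
            transform=self.transform,
            distance=self.distance,
        )
        res.degenerate = degenerate
        res.used_monte_carlo = unique_perms < 100
        return res


def _pearson3_tail(sample: np.ndarray, observed: float) -> float:
    """Upper-tail probability of `observed` under a Pearson type III
    distribution moment-matched to the permutation sample.

    Pseudo-F permutation distributions are positive and can be extremely
    heavy-tailed (interaction denominators with few df), so the fit is done
    on the log scale when possible (log-Pearson III), which tracks the
    empirical tail far better than a raw three-moment fit."""
    sample = sample[np.isfinite(sample)]
    if len(sample) < 10 or not np.isfinite(observed):
        return float("nan")
    if np.all(sample > 0) and observed > 0:
        sample = np.log(sample)
        observed = float(np.log(observed))
    m, sd = float(np.mean(sample)), float(np.std(sample))
    if sd == 0:
        return 1.0 if observed <= m else 0.0
    skew = float(sps.skew(sample))
    if abs(skew) < 1e-8:
        return float(sps.norm.sf(observed, loc=m, scale=sd))
    return float(sps.pearson3.sf(observed, skew, loc=m, scale=sd))


def permanova(
    table: pd.DataFrame,
    factors,
    response="D",
    random_factors=(),
    distance: str = "euclidean",
    transform: str = "log10",
    n_perm: int | str = 9999,
    seed: int | None = 0,
) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    model = Permanova(
        table, response, factors, random_factors=random_factors,
        transform=transform, distance=distance,
    )
    return model.fit(n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# pairwise a-posteriori permutation t-tests (Bonferroni)
# ---------------------------------------------------------------------------


def pairwise_posthoc(
    table: pd.DataFrame,
    factor: str = "technique",
    response: str = "D",
    transform: str = "log10",
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation t-tests between all level pairs of ``factor`` (other
    factors ignored, as in the source tables' footnotes), Bonferroni-adjusted
    by the number of pairs and capped at 1."""
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    y = _TRANSFORMS[transform](table[response].to_numpy())
    g = table[factor].to_numpy()
    for lev in levels:
        if (g == lev).sum() < 2:
            raise ValueError(f"level {lev!r} has fewer than 2 observations")
    rng = np.random.default_rng(int(seed) % (2**31))
    pairs = list(itertools.combinations(levels, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        ya, yb = y[g == a], y[g == b]
        t_obs = _pooled_t(ya, yb)
        pooled = np.concatenate([ya, yb])
        na = len(ya)
        count = 1
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(_pooled_t(pooled[:na], pooled[na:])) >= abs(t_obs) - 1e-12:
                count += 1
        p_raw = count / (n_perm + 1)
        rows.append(
            dict(
                level_a=a, level_b=b, t=t_obs, p_raw=p_raw,
                p_adjusted=min(1.0, n_pairs * p_raw),
            )
        )
    return pd.DataFrame(rows)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


# ---------------------------------------------------------------------------
# PERMDISP: homogeneity of multivariate dispersions
# ---------------------------------------------------------------------------


def _spatial_median(y: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Weiszfeld geometric median (coordinate median for 1-D input)."""
    if y.shape[1] == 1:
        return np.array([np.median(y[:, 0])])
    m = y.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(y - m, axis=1)
        if np.any(d < 1e-12):
            return m
        w = 1.0 / d
        new = (y * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def _anova_f(z: np.ndarray, g: np.ndarray, levels) -> float:
    gm = z.mean()
    ss_b = sum((z[g == lev].mean() - gm) ** 2 * (g == lev).sum() for lev in levels)
    ss_w = sum(((z[g == lev] - z[g == lev].mean()) ** 2).sum() for lev in levels)
    df_b = len(levels) - 1
    df_w = len(z) - len(levels)
    if ss_w <= 1e-300:
        return 0.0 if ss_b <= 1e-300 else np.inf
    return float((ss_b / df_b) / (ss_w / df_w))


def permdisp(
    table: pd.DataFrame,
    factor: str = "technique",
    response="D",
    transform: str = "log10",
    n_perm: int = 9999,
    seed: int = 0,
):
    """Permutation test of multivariate dispersion homogeneity: ANOVA F on
    distances of (transformed) observations to their group spatial median,
    with group labels permuted. Returns ``(F, p)``."""
    response = [response] if isinstance(response, str) else list(response)
    y = _TRANSFORMS[transform](table[response].to_numpy())
    if y.ndim == 1:
        y = y[:, None]
    g = table[factor].to_numpy()
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lev in levels:
        if (g == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has size < 2")
    z = np.empty(len(y))
    for lev in levels:
        sel = g == lev
        med = _spatial_median(y[sel])
        z[sel] = np.linalg.norm(y[sel] - med, axis=1)
    f_obs = _anova_f(z, g, levels)
    rng = np.random.default_rng(int(seed) % (2**31))
    count = 1
    gp = g.copy()
    for _ in range(n_perm):
        rng.shuffle(gp)
        if _anova_f(z, gp, levels) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / (n_perm + 1)


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementSummary:
    """Difference-plot summary of an alternative technique against the gold
    standard: differences (alt - reference), their median / IQR / 95% CI of
    the median (binomial order statistics), the mean-vs-difference pairs for
    plotting, and a rank-correlation trend indicator (reported, not tested)."""

    differences: np.ndarray
    means: np.ndarray
    labels: list
    median: float
    iqr: tuple
    ci95_median: tuple
    trend_rank_correlation: float

    def summary(self) -> str:
        return (
            f"Bland-Altman (n={len(self.differences)}): "
            f"median {self.median:.2f}; IQR: {self.iqr[0]:.2f}, {self.iqr[1]:.2f}; "
            f"95% CI: {self.ci95_median[0]:.2f}, {self.ci95_median[1]:.2f}; "
            f"trend rho {self.trend_rank_correlation:.2f}"
        )


def _median_ci(x: np.ndarray, level: float = 0.95):
    """Distribution-free CI of the median from binomial order statistics."""
    xs = np.sort(x)
    n = len(xs)
    alpha = (1 - level) / 2
    lo = int(sps.binom.ppf(alpha, n, 0.5))          # 0-based lower order stat
    hi = int(sps.binom.isf(alpha, n, 0.5))          # 0-based upper order stat
    lo = max(min(lo, n - 1), 0)
    hi = max(min(hi, n - 1), 0)
    return float(xs[lo]), float(xs[hi])


def bland_altman(reference_values, alternative_values, labels=None) -> AgreementSummary:
    """Agreement of an alternative measurement with a reference: difference
    plot summaries on the raw (mm) scale. Quartiles use the (n+1)p linear
    interpolation rule (Hyndman-Fan type 6, i.e. ``method="weibull"``); the
    median CI uses exact binomial order statistics."""
    ref = np.asarray(reference_values, float)
    alt = np.asarray(alternative_values, float)
    if ref.shape != alt.shape or ref.ndim != 1:
        raise ValueError("reference and alternative must be equal-length 1-D")
    if len(ref) < 2:
        raise ValueError("need at least two paired cases")
    diff = alt - ref
    means = 0.5 * (alt + ref)
    q1, q3 = np.quantile(diff, [0.25, 0.75], method="weibull")
    if np.ptp(diff) == 0 or np.ptp(means) == 0:
        rho = 0.0
    else:
        rho = float(sps.spearmanr(means, diff).statistic)
    return AgreementSummary(
        differences=diff,
        means=means,
        labels=list(labels) if labels is not None else list(range(len(diff))),
        median=float(np.median(diff)),
        iqr=(float(q1), float(q3)),
        ci95_median=_median_ci(diff),
        trend_rank_correlation=rho,
    )
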