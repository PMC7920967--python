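"""Patch-wise nested general linear models and max-statistic permutation tests.

For each surface patch p the feature y(p, i) (patch-mean expansion factor of
subject i) is modelled twice by ordinary least squares:

    null:        y = b0 + b_age*age + b_sex*sex + b_icv*ICV + e
    alternative: y = b0 + b_age*age + b_sex*sex + b_icv*ICV + b_resp*resp + e

and the test statistic is the residual-sum-of-squares ratio

    s_p = SSE_null(p) / SSE_alt(p)  >= 1,

a monotone transform of the partial F statistic for the response column:
s_p = 1 + F / (n - p_alt). Familywise error over the patches of a structure
is controlled by permutation: feature vectors are rearranged among subjects,
the maximum s_p over patches is recorded at each rearrangement, and a patch
is significant when its observed statistic exceeds the 95th percentile of
that max-statistic distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("HC", "R", "NR")
CONTRASTS = ("NR_vs_R", "NR_vs_HCandR")


@dataclass
class CovariateTable:
    """Per-subject covariates: id, age (years), sex (female=1, male=0),
    ICV (mm³), group in {HC, R, NR} (acute response), optional group_long
    (long-term response)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"id", "age", "sex", "icv", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        if df[list(required)].isna().any().any():
            raise ValueError("covariate table contains missing values")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if "group_long" in df.columns:
            bad = set(df["group_long"].dropna()) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown long-term group labels {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame["id"]]

    def groups(self, timepoint: str = "acute") -> pd.Series:
        if timepoint == "acute":
            return self.frame["group"]
        if timepoint == "long":
            if "group_long" not in self.frame.columns:
                raise ValueError("no group_long column for the long timepoint")
            return self.frame["group_long"]
        raise ValueError(f"unknown timepoint {timepoint!r}")

    @classmethod
    def load(cls, path: str) -> "CovariateTable":
        return cls(pd.read_csv(path))

    def save(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class Contrast:
    """A group comparison: which subjects enter the model and who gets
    response indicator 1.

    NR_vs_R: responders and non-responders only, indicator 1 for NR.
    NR_vs_HCandR: all subjects, indicator 1 for NR.
    """

    name: str
    timepoint: str = "acute"

    def __post_init__(self) -> None:
        if self.name not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.name!r}; expected one of {CONTRASTS}")

    def select(self, cov: CovariateTable) -> tuple[np.ndarray, np.ndarray]:
        """Return (subject mask over the table, response indicator on the
        selected subjects)."""
        g = cov.groups(self.timepoint).to_numpy()
        if self.name == "NR_vs_R":
            mask = np.isin(g, ["R", "NR"])
        else:
            mask = np.ones(len(g), dtype=bool)
        response = (g[mask] == "NR").astype(float)
        return mask, response


@dataclass
class GLMFit:
    """Per-patch OLS results: beta (patches x coefficients) and SSE (patches,)."""

    beta: np.ndarray
    sse: np.ndarray
    columns: list[str]


@dataclass
class PermutationResult:
    statistic: np.ndarray          # observed s_p per patch
    p_adjusted: np.ndarray         # FWER-adjusted p-values
    significant: np.ndarray        # bool per patch
    critical_value: float          # 95th-percentile max-statistic threshold
    max_distribution: np.ndarray   # permutation max statistics
    n_perm: int
    seed: int | None
    scheme: str
    exhaustive: bool = False


def build_design(
    cov: CovariateTable,
    contrast: Contrast,
    with_response: bool = True,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix for the selected subjects.

    Columns are ordered (intercept, age, sex, icv[, response]); continuous
    covariates enter unstandardized — s_p is invariant to affine rescaling
    of columns, and raw scale keeps the coefficients interpretable in
    expansion-factor units. Returns (X, column names, subject mask).
    """
    mask, response = contrast.select(cov)
    sub = cov.frame.loc[mask]
    cols = [np.ones(mask.sum()), sub["age"].to_numpy(float), sub["sex"].to_numpy(float), sub["icv"].to_numpy(float)]
    names = ["intercept", "age", "sex", "icv"]
    if with_response:
        cols.append(response)
        names.append("response")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _find_collinear(X, names)
        raise ValueError(f"design matrix rank deficient: column {collinear!r} is collinear")
    return X, names, mask


def _find_collinear(X: np.ndarray, names: list[str]) -> str:
    for j in range(1, X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            return names[j]
    return names[-1]


def fit_glm(Y: np.ndarray, X: np.ndarray, columns: list[str] | None = None) -> GLMFit:
    """Ordinary least squares of each patch row of Y (patches x subjects)
    on the shared design X (subjects x covariates)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[1] != X.shape[0]:
        raise ValueError(f"Y has {Y.shape[1]} subjects but X has {X.shape[0]} rows")
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer subjects than design columns")
    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix rank deficient")
    resid = Y.T - X @ beta
    sse = np.einsum("ij,ij->j", resid, resid)
    if columns is None:
        columns = [f"b{j}" for j in range(X.shape[1])]
    return GLMFit(beta.T, sse, list(columns))


def _residual_maker(X: np.ndarray) -> np.ndarray:
    """I - X (X'X)^-1 X' via QR (symmetric idempotent)."""
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


def sse_ratio(Y: np.ndarray, X_null: np.ndarray, X_alt: np.ndarray) -> np.ndarray:
    """Per-patch s_p = SSE_null / SSE_alt for the nested designs.

    A patch fit perfectly by the alternative model (SSE_alt == 0) gets
    s_p = +inf with a warning; the permutation machinery treats it as
    always-maximal.
    """
    Y2 = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    sse_null = fit_glm(Y2, X_null).sse
    sse_alt = fit_glm(Y2, X_alt).sse
    # an SSE at round-off level relative to the data is a perfect fit
    tiny = 1e-24 * np.einsum("ij,ij->i", Y2, Y2)
    zero_alt = sse_alt <= tiny
    zero_null = sse_null <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(zero_alt, np.inf, sse_null / np.where(zero_alt, 1.0, sse_alt))
    s = np.where(zero_alt & zero_null, 1.0, s)
    if np.isinf(s).any():
        warnings.warn("SSE_alt is zero in some patch: s_p reported as +inf", RuntimeWarning)
    # guard against round-off dipping below the nested-model bound
    return np.maximum(s, 1.0)


def _batched_sse(Yt: np.ndarray, M: np.ndarray) -> np.ndarray:
    """SSE per (batch, patch) for residual maker M: Yt is (B, patches, n)."""
    R = Yt @ M  # M symmetric
    return np.einsum("bpn,bpn->bp", R, R)


def max_stat_permutation(
    Y: np.ndarray,
    cov: CovariateTable,
    contrast: Contrast,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "shuffle_features",
    alpha: float = 0.05,
    batch: int = 512,
) -> PermutationResult:
    """Max-statistic permutation test of the response effect over all patches.

    ``shuffle_features`` rearranges whole feature vectors y_i among the
    subjects (the study's literal scheme); ``freedman_lane`` permutes only
    the null-model residuals, preserving the covariate structure. When the
    total number of distinct permutations is at most ``n_perm`` the test
    enumerates them exhaustively instead of sampling (with a warning).

    Adjusted p-values use the (1+b)/(1+B) convention; a patch is significant
    exactly when its adjusted p is below ``alpha``, equivalently when its
    statistic strictly exceeds the reported critical value (the matching
    upper order statistic of the max distribution).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if scheme not in ("shuffle_features", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    X_alt, names, mask = build_design(cov, contrast, with_response=True)
    X_null = X_alt[:, :-1]
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))[:, mask]
    n = X_alt.shape[0]

    obs = sse_ratio(Y, X_null, X_alt)

    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        warnings.warn(
            f"only {len(perms)} distinct permutations for n={n}; enumerating exhaustively",
            RuntimeWarning,
        )
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    B = len(perms)

    M_null = _residual_maker(X_null)
    M_alt = _residual_maker(X_alt)
    H_null = np.eye(n) - M_null

    max_stats = np.empty(B)
    if scheme == "freedman_lane":
        fitted = Y @ H_null.T
        resid = Y @ M_null.T
    for lo in range(0, B, batch):
        pr = perms[lo : lo + batch]
        if scheme == "shuffle_features":
            Yb = Y[:, pr].transpose(1, 0, 2)  # (b, patches, n)
        else:
            Yb = fitted[None, :, :] + resid[:, pr].transpose(1, 0, 2)
        sse_n = _batched_sse(Yb, M_null)
        sse_a = _batched_sse(Yb, M_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(sse_a > 0, sse_n / np.where(sse_a > 0, sse_a, 1.0), np.inf)
        s = np.where((sse_a == 0) & (sse_n == 0), 1.0, s)
        max_stats[lo : lo + batch] = np.maximum(s, 1.0).max(axis=1)

    exceed = (max_stats[None, :] >= obs[:, None]).sum(axis=1)
    p_adj = (1.0 + exceed) / (1.0 + B)
    # significance threshold consistent with p_adj < alpha including ties:
    # b <= K exceedances, K the largest integer with (1+K)/(1+B) < alpha
    K = int(math.ceil(alpha * (1 + B) - 1 - 1e-9)) - 1
    sig = exceed <= K
    desc = np.sort(max_stats)[::-1]
    critical = float(desc[K]) if 0 <= K < B else float("inf")
    return PermutationResult(
        statistic=obs,
        p_adjusted=p_adj,
        significant=sig,
        critical_value=critical,
        max_distribution=max_stats,
        n_perm=B,
        seed=seed,
        scheme=scheme,
        exhaustive=exhaustive,
    )


def percent_atrophy(
    Y: np.ndarray, cov: CovariateTable, patch: int, timepoint: str = "acute"
) -> float:
    """Percent atrophy of one patch in non-responders relative to everyone
    else: 100 * (1 - mean_NR / mean_others) of the patch expansion factors."""
    g = cov.groups(timepoint).to_numpy()
    y = np.atleast_2d(np.asarray(Y, dtype=np.float64))[patch]
    nr = y[g == "NR"].mean()
    other = y[g != "NR"].mean()
    return float(100.0 * (1.0 - nr / other))


def report_contrasts(
    features: dict[str, "object"],
    cov: CovariateTable,
    contrasts: list[str] | None = None,
    timepoints: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "shuffle_features",
) -> pd.DataFrame:
    """Minimum adjusted p-value per structure x contrast x timepoint.

    ``features`` maps structure name to a FeatureMatrix (or bare array whose
    columns follow the covariate table's subject order). Returns a tidy
    table with the per-structure minimum adjusted p, the patch achieving it,
    its statistic, and a significance flag at 0.05.
    """
    if contrasts is None:
        contrasts = list(CONTRASTS)
    if timepoints is None:
        timepoints = ["acute"]
        if "group_long" in cov.frame.columns:
            timepoints.append("long")
    rows = []
    for struct, fm in features.items():
        Y = fm.values if hasattr(fm, "values") else np.asarray(fm)
        for cname in contrasts:
            for tp in timepoints:
                res = max_stat_permutation(
                    Y, cov, Contrast(cname, timepoint=tp),
                    n_perm=n_perm, seed=seed, scheme=scheme,
                )
                best = int(np.argmin(res.p_adjusted))
                rows.append(
                    {
                        "structure": struct,
                        "contrast": cname,
                        "timepoint": tp,
                        "patch": best,
                        "s_p": float(res.statistic[best]),
                        "min_p_adj": float(res.p_adjusted[best]),
                        "significant": bool(res.significant[best]),
                    }
                )
    return pd.DataFrame(rows)
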