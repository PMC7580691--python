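"""DIA-style quantification chain and two-group differential analysis.

The quantification chain mirrors how DIA software rolls up signal: fragment
peak areas sum to peptide intensities, peptide intensities sum to protein
intensities per run; identifications are kept at a q-value cutoff; and runs
are rescaled by median-based factors to remove systematic LC-MS drift, under
the assumption that most peptides are not regulated across runs.

Differential analysis between the two groups ("before" vs "after"
treatment) uses per-protein fold changes from geometric group means on the
log2 scale, a strict fold-change threshold to call differentially expressed
proteins (DEPs), an OPLS-DA decomposition with a permutation test for the
group separation, and per-protein Welch t-tests as the validation
statistic.

Also here: variable-width DIA isolation-window design that equalises the
precursor count per window via quantiles of the precursor m/z distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("before", "after")


class ConfigurationError(ValueError):
    pass


@dataclass
class RunMatrix:
    """Protein × run intensity matrix with group labels.

    ``data`` holds non-negative intensities (NaN = missing), indexed by
    protein accession with one column per run. ``groups`` maps each run id
    to "before" or "after". ``qvalues`` optionally carries a per-protein
    identification q-value.
    """

    data: pd.DataFrame
    groups: pd.Series
    qvalues: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [c for c in self.data.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"runs without a group label: {missing}")
        bad = set(self.groups.loc[list(self.data.columns)]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def runs_in(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]

    def copy(self) -> "RunMatrix":
        return RunMatrix(
            self.data.copy(),
            self.groups.copy(),
            None if self.qvalues is None else self.qvalues.copy(),
        )


@dataclass(frozen=True)
class DepResult:
    accession: str
    fc: float
    direction: str  # up | down | null
    log2_mean_before: float
    log2_mean_after: float
    p_value: float | None = None


@dataclass
class OplsdaResult:
    predictive_scores: pd.Series  # run -> t
    orthogonal_scores: pd.DataFrame  # run × orthogonal component
    r2x_predictive: float
    r2x_orthogonal: float
    separation: float
    permutation_p: float
    n_permutations: int


@dataclass(frozen=True)
class IsolationWindow:
    lower_mz: float
    upper_mz: float
    precursor_count: int


# ---------------------------------------------------------------------------
# roll-up and filtering

def rollup(fragment_table: pd.DataFrame, level: str = "protein") -> RunMatrix:
    """Fragment areas → peptide intensities → protein × run matrix.

    Accepts a fragment-level table (with ``fragment_id``) or directly a
    peptide-level table; sums are over whatever rows are present, so missing
    fragments or peptides are simply absent from the totals. With
    ``level="peptide"`` the roll-up stops at peptides (rows keyed by
    protein + peptide), which is the right granularity for estimating
    cross-run normalization factors.
    """
    if level not in {"protein", "peptide"}:
        raise ConfigurationError(f"unknown rollup level: {level}")
    if (fragment_table["intensity"] < 0).any():
        raise ValueError("negative areas in fragment table")
    peptide = fragment_table.groupby(
        ["protein_accession", "peptide_sequence", "run_id", "group"], as_index=False
    )["intensity"].sum()
    if level == "peptide":
        data = peptide.pivot_table(
            index=["protein_accession", "peptide_sequence"],
            columns="run_id",
            values="intensity",
            aggfunc="sum",
        )
    else:
        protein = peptide.groupby(["protein_accession", "run_id"])["intensity"].sum()
        data = protein.unstack("run_id")
    groups = fragment_table[["run_id", "group"]].drop_duplicates()
    groups = pd.Series(groups.group.to_numpy(), index=groups.run_id.to_numpy())
    return RunMatrix(data=data, groups=groups)


def qvalue_filter(matrix: RunMatrix, cutoff: float = 0.01) -> RunMatrix:
    """Keep rows with q ≤ cutoff; pass through (loudly) when no q-values."""
    if matrix.qvalues is None:
        logger.warning("no q-values on matrix; q-value filter skipped")
        return matrix
    q = matrix.qvalues.reindex(matrix.data.index)
    keep = q <= cutoff
    removed = int((~keep).sum())
    logger.info("q-value filter at %g removed %d of %d rows", cutoff, removed, len(keep))
    return RunMatrix(matrix.data.loc[keep], matrix.groups, q.loc[keep])


def cross_run_normalize(
    matrix: RunMatrix,
    mode: str = "global_median",
    rt: pd.Series | None = None,
    n_bins: int = 10,
    factor_source: RunMatrix | None = None,
) -> tuple[RunMatrix, pd.Series]:
    """Remove multiplicative per-run bias by median equalisation.

    ``global_median``: each run is divided by a factor chosen so the per-run
    median log-intensity over rows observed in every run is equalised;
    factors are anchored so the least-biased run has factor 1.
    ``rt_local``: the same computation within retention-time bins (``rt``
    gives a retention time per row), with log-factors interpolated between
    bin centers. Returns the normalised matrix and the factors applied.

    ``factor_source`` optionally supplies a finer-grained matrix (same runs,
    e.g. peptide-level rows) from which the factors are estimated before
    being applied to ``matrix`` — more rows give a steadier median.
    """
    if factor_source is not None:
        if mode != "global_median":
            raise ConfigurationError("factor_source only supports global_median")
        _, factors = cross_run_normalize(factor_source, mode=mode)
        factors = factors.loc[list(matrix.data.columns)]
        norm = matrix.data.div(factors, axis=1)
        return RunMatrix(norm, matrix.groups, matrix.qvalues), factors
    if matrix.data.shape[1] < 2:
        raise ValueError("normalization needs at least two runs")
    if mode not in {"global_median", "rt_local"}:
        raise ConfigurationError(f"unknown normalization mode: {mode}")

    def _factors(block: pd.DataFrame) -> pd.Series:
        complete = block.dropna()
        complete = complete[(complete > 0).all(axis=1)]
        if complete.empty:
            logger.warning(
                "no rows complete in all runs; falling back to pairwise medians"
            )
            ref = block.columns[0]
            logf = {}
            for c in block.columns:
                pair = block[[ref, c]].dropna()
                pair = pair[(pair > 0).all(axis=1)]
                logf[c] = float(np.median(np.log(pair[c]) - np.log(pair[ref]))) if len(pair) else 0.0
            logf = pd.Series(logf)
        else:
            # median of row-centered log intensities: the per-row term cancels
            # exactly, so the estimate is insensitive to the intensity
            # distribution's shape and robust to symmetric regulation
            ld = np.log(complete)
            centered = ld.sub(ld.mean(axis=1), axis=0)
            med = centered.median(axis=0)
            logf = med - med.median()
        return np.exp(logf - logf.min())

    if mode == "global_median":
        factors = _factors(matrix.data)
        norm = matrix.data.div(factors, axis=1)
        return RunMatrix(norm, matrix.groups, matrix.qvalues), factors

    if rt is None:
        raise ConfigurationError("rt_local normalization requires an rt series")
    rt = rt.reindex(matrix.data.index)
    edges = np.quantile(rt.dropna(), np.linspace(0, 1, n_bins + 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    log_factors = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (rt >= lo) & (rt <= hi)
        f = _factors(matrix.data.loc[sel]) if sel.sum() >= 2 else None
        log_factors.append(np.log(f) if f is not None else None)
    # fill empty bins from the global factors
    global_log = np.log(_factors(matrix.data))
    log_factors = [global_log if lf is None else lf for lf in log_factors]
    norm = matrix.data.copy()
    for col in norm.columns:
        col_lf = np.array([lf[col] for lf in log_factors])
        row_lf = np.interp(rt.to_numpy(dtype=float), centers, col_lf)
        norm[col] = norm[col] / np.exp(row_lf)
    mean_factors = pd.Series(
        {c: float(np.exp(np.mean([lf[c] for lf in log_factors]))) for c in norm.columns}
    )
    return RunMatrix(norm, matrix.groups, matrix.qvalues), mean_factors


# ---------------------------------------------------------------------------
# fold change and DEP calling

def _log2_with_pseudocount(matrix: RunMatrix) -> pd.DataFrame:
    """log2 intensities; zeros replaced by half the smallest positive value."""
    data = matrix.data
    positive_min = np.nanmin(data.to_numpy()[data.to_numpy() > 0]) if (data.to_numpy() > 0).any() else 1.0
    pseudo = positive_min / 2.0
    return np.log2(data.where(data > 0, pseudo).where(data.notna()))


def fold_change(matrix: RunMatrix, method: str = "geometric") -> pd.DataFrame:
    """Per-protein after/before fold change.

    ``geometric`` (default): fc = 2^(mean log2 after − mean log2 before);
    ``arithmetic``: ratio of arithmetic group means. Proteins lacking any
    observation in one group are flagged (``insufficient`` = True) with
    fc = NaN rather than silently dropped.
    """
    if method not in {"geometric", "arithmetic"}:
        raise ConfigurationError(f"unknown fold-change method: {method}")
    before_runs = matrix.runs_in("before")
    after_runs = matrix.runs_in("after")
    if not before_runs or not after_runs:
        raise ValueError("both groups must be present")
    log2d = _log2_with_pseudocount(matrix)
    mb = log2d[before_runs].mean(axis=1, skipna=True)
    ma = log2d[after_runs].mean(axis=1, skipna=True)
    n_b = matrix.data[before_runs].notna().sum(axis=1)
    n_a = matrix.data[after_runs].notna().sum(axis=1)
    insufficient = (n_b < 1) | (n_a < 1)
    if method == "geometric":
        fc = np.power(2.0, ma - mb)
    else:
        fc = matrix.data[after_runs].mean(axis=1, skipna=True) / matrix.data[
            before_runs
        ].mean(axis=1, skipna=True)
    fc = fc.where(~insufficient)
    out = pd.DataFrame(
        {
            "accession": matrix.data.index,
            "fc": fc.to_numpy(),
            "log2_mean_before": mb.to_numpy(),
            "log2_mean_after": ma.to_numpy(),
            "insufficient": insufficient.to_numpy(),
        }
    )
    return out


def select_deps(
    results: pd.DataFrame, threshold: float = 1.5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition proteins by fold change with strict inequalities.

    up: fc > threshold; down: fc < 1/threshold; everything else (including
    fc exactly at the boundary and unquantifiable rows) is null.
    """
    if threshold <= 1:
        raise ConfigurationError("fold-change threshold must be > 1")
    fc = results["fc"]
    direction = np.where(
        fc > threshold, "up", np.where(fc < 1.0 / threshold, "down", "null")
    )
    direction = np.where(fc.isna(), "null", direction)
    out = results.copy()
    out["direction"] = direction
    counts = {
        "up": int((direction == "up").sum()),
        "down": int((direction == "down").sum()),
        "null": int((direction == "null").sum()),
    }
    return out, counts


def validation_test(matrix: RunMatrix) -> pd.DataFrame:
    """Two-sided Welch t-test on log2 intensities per protein.

    Degenerate rows (zero variance in both groups, or fewer than two
    observations in a group) get p = 1 with ``degenerate`` flagged.
    """
    before_runs = matrix.runs_in("before")
    after_runs = matrix.runs_in("after")
    log2d = _log2_with_pseudocount(matrix)
    rows = []
    for acc in matrix.data.index:
        a = log2d.loc[acc, after_runs].dropna().to_numpy(dtype=float)
        b = log2d.loc[acc, before_runs].dropna().to_numpy(dtype=float)
        degenerate = len(a) < 2 or len(b) < 2 or (np.var(a) == 0 and np.var(b) == 0)
        if degenerate:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if math.isnan(p):
                p, degenerate = 1.0, True
        rows.append({"accession": acc, "p_value": p, "degenerate": degenerate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OPLS-DA

def _opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """NIPALS-style OPLS: strip y-orthogonal variation, then one predictive
    component. X must be centered. Returns (t_pred, T_ortho, r2x_pred, r2x_ortho)."""
    Xd = X.copy()
    ssx = (X**2).sum()
    T_ortho = []
    r2x_ortho = 0.0
    for _ in range(n_orthogonal):
        w = Xd.T @ y / (y @ y)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_ortho.append(t_o)
        r2x_ortho += float((np.outer(t_o, p_o) ** 2).sum() / ssx) if ssx > 0 else 0.0
    w = Xd.T @ y / (y @ y)
    nw = np.linalg.norm(w)
    w = w / nw if nw > 0 else w
    t = Xd @ w
    p = Xd.T @ t / (t @ t) if (t @ t) > 0 else np.zeros(X.shape[1])
    r2x_pred = float((np.outer(t, p) ** 2).sum() / ssx) if ssx > 0 else 0.0
    T = np.column_stack(T_ortho) if T_ortho else np.empty((X.shape[0], 0))
    return t, T, r2x_pred, r2x_ortho


def _separation_statistic(t: np.ndarray, y: np.ndarray) -> float:
    """Between-group distance of predictive scores over pooled within-group
    spread; large when the two groups separate along the predictive axis."""
    g1, g2 = t[y > 0], t[y < 0]
    spread = math.sqrt((np.var(g1, ddof=1) + np.var(g2, ddof=1)) / 2.0)
    diff = abs(g1.mean() - g2.mean())
    if spread == 0:
        return math.inf if diff > 0 else 0.0
    return diff / spread


def _distinct_label_permutations(y: np.ndarray) -> list[np.ndarray]:
    """All relabelings of runs preserving group sizes, excluding the
    observed one.

    The separation statistic is symmetric under a global label swap, so for
    balanced designs each unordered partition is enumerated once (the side
    containing the first run represents it).
    """
    from itertools import combinations

    n = len(y)
    k = int((y > 0).sum())
    perms = []
    for combo in combinations(range(n), k):
        if 2 * k == n and 0 not in combo:
            continue  # mirror of a partition already listed
        yp = -np.ones(n)
        yp[list(combo)] = 1.0
        if np.array_equal(yp, y) or (2 * k == n and np.array_equal(-yp, y)):
            continue
        perms.append(yp)
    return perms


def oplsda(
    matrix: RunMatrix,
    n_orthogonal: int = 1,
    n_permutations: int = 999,
    seed: int | None = 0,
    scale: str = "center",
    log_transform: bool = True,
) -> OplsdaResult:
    """OPLS-DA of runs against the binary group vector, with a permutation
    test of the group-separation statistic.

    Rows with missing values are median-imputed per protein. ``scale`` is
    ``"center"`` (mean-centering, the default) or ``"uv"`` (unit variance).
    The permutation p-value uses the add-one estimator
    (1 + #{stat_perm ≥ stat_obs}) / (1 + n_permutations), so its floor is
    1/(n_permutations + 1). When the design admits no more than
    ``n_permutations`` distinct relabelings (small run counts), the test is
    exact: all distinct partitions other than the observed one are
    enumerated and ``n_permutations`` reflects that count. Score signs are
    indeterminate (as in any latent variable model).
    """
    runs = list(matrix.data.columns)
    y = np.array([1.0 if matrix.groups[r] == "after" else -1.0 for r in runs])
    if (y > 0).sum() < 2 or (y < 0).sum() < 2:
        raise ValueError("need at least two runs per group")
    if len(runs) <= n_orthogonal + 1:
        raise ValueError("fewer runs than requested components")
    if scale not in {"center", "uv"}:
        raise ConfigurationError(f"unknown scaling: {scale}")

    data = matrix.data
    if log_transform:
        data = _log2_with_pseudocount(matrix)
    # per-protein median imputation of missing runs
    med = data.median(axis=1, skipna=True)
    data = data.apply(lambda col: col.fillna(med))
    data = data.dropna(axis=0)  # rows missing everywhere

    X = data.to_numpy(dtype=float).T  # runs × proteins
    X = X - X.mean(axis=0)
    if scale == "uv":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd

    yc = y - y.mean()
    t, T_ortho, r2x_pred, r2x_ortho = _opls_fit(X, yc, n_orthogonal)
    observed = _separation_statistic(t, y)

    distinct = _distinct_label_permutations(y)
    if len(distinct) <= n_permutations:
        perms = distinct  # exact test over every distinct relabeling
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(y) for _ in range(n_permutations)]
    exceed = 0
    for yp in perms:
        ypc = yp - yp.mean()
        tp, _, _, _ = _opls_fit(X, ypc, n_orthogonal)
        if _separation_statistic(tp, yp) >= observed:
            exceed += 1
    n_used = len(perms)
    p = (1.0 + exceed) / (1.0 + n_used)

    return OplsdaResult(
        predictive_scores=pd.Series(t, index=runs),
        orthogonal_scores=pd.DataFrame(
            T_ortho, index=runs, columns=[f"ortho_{i+1}" for i in range(T_ortho.shape[1])]
        ),
        r2x_predictive=r2x_pred,
        r2x_orthogonal=r2x_ortho,
        separation=observed,
        permutation_p=p,
        n_permutations=n_used,
    )


# ---------------------------------------------------------------------------
# DIA isolation-window design

def design_dia_windows(
    precursor_mzs: Sequence[float],
    n_windows: int = 38,
    mz_range: tuple[float, float] = (400.0, 900.0),
) -> list[IsolationWindow]:
    """Variable-width isolation windows equalising the precursor count.

    Window boundaries sit at the k/n quantiles of the in-range precursor m/z
    distribution: the sorted precursors are split into ``n_windows`` nearly
    equal chunks (sizes differ by at most one) and boundaries are placed
    midway between adjacent chunk extremes. Windows are contiguous and cover
    ``mz_range`` exactly.
    """
    lo, hi = mz_range
    if not lo < hi:
        raise ConfigurationError("empty m/z range")
    mz = np.sort(np.asarray([m for m in precursor_mzs if lo <= m <= hi], dtype=float))
    if len(mz) < n_windows:
        raise ValueError(
            f"need at least {n_windows} precursors in range, got {len(mz)}"
        )
    chunks = np.array_split(mz, n_windows)
    bounds = [lo]
    for a, b in zip(chunks[:-1], chunks[1:]):
        bounds.append(0.5 * (a[-1] + b[0]))
    bounds.append(hi)
    return [
        IsolationWindow(lower_mz=float(l), upper_mz=float(u), precursor_count=len(c))
        for l, u, c in zip(bounds[:-1], bounds[1:], chunks)
    ]


def windows_to_frame(windows: Sequence[IsolationWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lower_mz": w.lower_mz, "upper_mz": w.upper_mz, "count": w.precursor_count}
            for w in windows
        ]
    )


# ---------------------------------------------------------------------------
# matrix I/O (protein × run TSV with a two-line header: run id, group)

def write_run_matrix(matrix: RunMatrix, path) -> None:
    index_name = matrix.data.index.name or "accession"
    with open(path, "w") as fh:
        fh.write(f"{index_name}\t" + "\t".join(map(str, matrix.data.columns)) + "\n")
        fh.write(
            "group\t" + "\t".join(matrix.groups[c] for c in matrix.data.columns) + "\n"
        )
        matrix.data.to_csv(fh, sep="\t", header=False)


def read_run_matrix(path) -> RunMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        index_name, header = first[0], first[1:]
        groups = fh.readline().rstrip("\n").split("\t")[1:]
        data = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    data.columns = header
    data.index.name = index_name
    return RunMatrix(data, pd.Series(groups, index=header))
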