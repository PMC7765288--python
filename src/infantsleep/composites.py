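"""Sleep composites: imputation, PCA with promax rotation, pruning,
composite scoring and Rubin pooling.

The assessment matrix (one row per participant-timepoint, one column per
sleep variable) is z-scored over all pooled assessments and decomposed by
principal components; the component loading matrix is obliquely rotated
(promax) so the five composites may correlate.  Variables whose largest
absolute loading falls below a cutoff (default 0.512, a conventional
threshold for samples above 100) are dropped, the solution is refit on
the retained set, and each variable is assigned to its strongest
component with the sign of that loading.  A composite score is the
unweighted mean of its variables' z-scores, sign-aligned so that the
composite's printed direction is preserved.

Promax rotation and Horn's parallel analysis are implemented here
directly (varimax -> power-4 target -> Procrustes fit, following the
classic construction also used by R's ``stats::promax``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPOSITE_NAMES = ("Sleep Activity", "Sleep Variability", "Sleep Day",
                   "Sleep Timing", "Sleep Night")

DEFAULT_LOADING_CUTOFF = 0.512

#: Variable ids dropped in the reference infant-cohort solution this
#: pipeline operationalizes: 14 variables whose largest absolute promax
#: loading fell below 0.512 ...
REFERENCE_LOW_LOADING_IDS = (7, 8, 20, 26, 29, 31, 35, 37, 39, 41, 42, 43,
                             45, 46)
#: ... plus Sleep Duration 24 h, removed for interpretability (it loaded
#: with the daytime composite, blurring the day/night split).
REFERENCE_INTERPRETABILITY_DROP_IDS = (38,)
#: The 33 variables retained in the reference five-composite solution.
REFERENCE_RETAINED_IDS = tuple(
    i for i in range(1, 49)
    if i not in REFERENCE_LOW_LOADING_IDS
    and i not in REFERENCE_INTERPRETABILITY_DROP_IDS)

#: Per-composite variance proportions of the reference solution, in the
#: order of COMPOSITE_NAMES' reference table (Activity, Variability, Day,
#: Timing, Night).
REFERENCE_VARIANCE_PROPORTIONS = (0.19, 0.14, 0.14, 0.13, 0.11)

#: Reference assignment of the retained variables to the five composites
#: (strongest-loading component per variable, with the loading's sign).
REFERENCE_ASSIGNMENT = {
    "Sleep Activity": {19: -1, 23: 1, 21: 1, 25: 1, 30: -1, 27: 1, 22: 1,
                       24: 1, 48: -1, 28: 1},
    "Sleep Variability": {14: 1, 16: 1, 18: 1, 10: 1, 12: 1, 4: 1, 6: 1,
                          2: 1},
    "Sleep Day": {32: -1, 34: 1, 36: 1, 47: -1, 40: 1, 33: -1, 44: -1},
    "Sleep Timing": {9: 1, 3: 1, 11: 1, 5: 1, 1: 1},
    "Sleep Night": {15: 1, 13: 1, 17: 1},
}


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def impute(matrix: pd.DataFrame, m: int = 5, iterations: int = 10,
           seed: int = 0, max_missing_frac: float = 0.5) -> list[pd.DataFrame]:
    """Multiple imputation of the assessment matrix.

    Chained equations with predictive mean matching (statsmodels
    ``MICEData``) stand behind this contract; every numeric column with
    missing cells is imputed from all other columns (include age/sex
    covariate columns in ``matrix`` to condition on them).  Returns ``m``
    completed copies; observed cells are identical across copies and the
    whole set is deterministic given ``seed``.
    """
    from statsmodels.imputation.mice import MICEData

    if matrix.isna().all().any():
        bad = matrix.columns[matrix.isna().all()].tolist()
        raise ValueError(f"columns with no observed values: {bad}")
    frac = matrix.isna().mean()
    if (frac > max_missing_frac).any():
        bad = frac[frac > max_missing_frac].index.tolist()
        raise ValueError(f"missingness above ceiling in: {bad}")

    if not matrix.isna().any().any():
        return [matrix.copy() for _ in range(m)]

    data = matrix.copy()
    data.columns = [f"c{i}" for i in range(len(matrix.columns))]
    rng_state = np.random.get_state()
    np.random.seed(seed % (2 ** 31))
    try:
        mice = MICEData(data.reset_index(drop=True))
        out = []
        for _ in range(m):
            mice.update_all(iterations)
            done = mice.data.copy()
            done.columns = matrix.columns
            done.index = matrix.index
            out.append(done)
    finally:
        np.random.set_state(rng_state)
    return out


# ---------------------------------------------------------------------------
# component count: parallel analysis + scree
# ---------------------------------------------------------------------------

def _corr_eigvals(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x, rowvar=False)
    return np.sort(np.linalg.eigvalsh(c))[::-1]


def choose_k(matrix: pd.DataFrame, n_iter: int = 100,
             quantile: float = 0.95, seed: int = 0) -> dict:
    """Suggest a component count by Horn's parallel analysis.

    Observed correlation-matrix eigenvalues are compared with the given
    quantile of eigenvalues from ``n_iter`` standard-normal matrices of
    the same shape; the suggestion is the number of leading observed
    eigenvalues exceeding their random counterpart.  Scree diagnostics
    (both eigenvalue series) are returned alongside.
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("choose_k requires a complete matrix (impute first)")
    n, p = x.shape
    obs = _corr_eigvals(x)
    rng = np.random.default_rng(seed)
    rand = np.empty((n_iter, p))
    for i in range(n_iter):
        rand[i] = _corr_eigvals(rng.standard_normal((n, p)))
    thresh = np.quantile(rand, quantile, axis=0)
    above = obs > thresh
    k = int(np.argmin(above)) if not above.all() else p
    return {"k": k, "eigenvalues": obs, "random_quantiles": thresh,
            "n": n, "p": p}


# ---------------------------------------------------------------------------
# rotation machinery
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser-normalized by default).

    Returns (rotated loadings, rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if normalize:
        comm = np.sqrt((L ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    Lr = L @ R
    if normalize:
        Lr = Lr * comm[:, None]
    return Lr, R


def promax(loadings: np.ndarray, power: int = 4
           ) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation.

    Varimax first, then each loading is raised to ``power`` (sign kept)
    to form an idealized target, and the varimax solution is rotated onto
    it by least squares; columns are rescaled so the implied factors have
    unit variance.  Returns (pattern matrix, factor correlation matrix).
    """
    V, _ = varimax(loadings)
    # column sign convention: strongest loading positive
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    Q = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def fit_pca_promax(matrix: pd.DataFrame, k: int = 5, power: int = 4
                   ) -> dict:
    """Principal components of the z-scored matrix, promax-rotated.

    Returns a dict with the pattern matrix (DataFrame, variables x
    components), factor correlations, unrotated loadings and per-component
    variance proportions (sum of squared pattern loadings / n variables).
    Component columns are sign-fixed so each component's largest-|loading|
    variable loads positive.
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("fit_pca_promax requires a complete matrix")
    n, p = x.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(n, p)}")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:k]
    load = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))

    if k == 1:
        pattern, phi = load, np.eye(1)
    else:
        pattern, phi = promax(load, power=power)
    signs = np.sign(pattern[np.argmax(np.abs(pattern), axis=0),
                            np.arange(k)])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)

    cols = [f"PC{i + 1}" for i in range(k)]
    pat = pd.DataFrame(pattern, index=matrix.columns, columns=cols)
    var_prop = (pattern ** 2).sum(axis=0) / p
    return {"pattern": pat, "phi": pd.DataFrame(phi, index=cols, columns=cols),
            "unrotated": pd.DataFrame(load, index=matrix.columns, columns=cols),
            "variance_proportion": pd.Series(var_prop, index=cols),
            "eigenvalues": eigval[np.argsort(eigval)[::-1]]}


# ---------------------------------------------------------------------------
# pruning, assignment, scoring
# ---------------------------------------------------------------------------

@dataclass
class CompositeSolution:
    """Rotated solution with variable assignment and composite scores."""

    loadings: pd.DataFrame               # retained variables x components
    assignment: dict = field(default_factory=dict)  # var -> (component, sign)
    retained: list = field(default_factory=list)
    dropped_low_loading: list = field(default_factory=list)
    drop_list: list = field(default_factory=list)
    phi: pd.DataFrame | None = None
    variance_proportion: pd.Series | None = None
    component_labels: dict = field(default_factory=dict)  # column -> name
    scores: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def members(self, component: str) -> list:
        return [v for v, (c, _s) in self.assignment.items() if c == component]


def prune_and_assign(matrix: pd.DataFrame, k: int = 5,
                     cutoff: float = DEFAULT_LOADING_CUTOFF,
                     drop_list: tuple = (), refit: bool = True,
                     power: int = 4) -> CompositeSolution:
    """Fit, prune low-loading variables, refit, and assign variables.

    Variables in ``drop_list`` are removed a priori; variables whose
    maximum absolute pattern loading is below ``cutoff`` are removed
    data-driven; with ``refit`` the rotation is re-estimated on the
    retained set (the loadings reported are always from the final fit).
    Each retained variable is assigned to its max-|loading| component
    with the sign of that loading.
    """
    work = matrix.drop(columns=list(drop_list), errors="ignore")
    fit = fit_pca_promax(work, k=k, power=power)
    absmax = fit["pattern"].abs().max(axis=1)
    low = absmax[absmax < cutoff].index.tolist()
    retained = [c for c in work.columns if c not in low]
    if refit and low:
        fit = fit_pca_promax(work[retained], k=k, power=power)
    pat = fit["pattern"].loc[retained]

    assignment = {}
    for var in retained:
        row = pat.loc[var]
        comp = row.abs().idxmax()
        assignment[var] = (comp, 1 if row[comp] >= 0 else -1)
    counts = {c: sum(1 for v, (cc, _s) in assignment.items() if cc == c)
              for c in pat.columns}
    if min(counts.values(), default=0) < 1:
        empty = [c for c, n in counts.items() if n < 1]
        raise ValueError(f"components with no assigned variable: {empty}")

    return CompositeSolution(
        loadings=pat, assignment=assignment, retained=retained,
        dropped_low_loading=low, drop_list=list(drop_list),
        phi=fit["phi"], variance_proportion=fit["variance_proportion"])


def label_components(solution: CompositeSolution,
                     registry=None) -> CompositeSolution:
    """Attach the field's five composite names to the fitted components.

    Components are labelled by the content of their assigned variables:
    mostly cross-day variability slots -> Sleep Variability; clock-time
    variables -> Sleep Timing; daytime-window variables -> Sleep Day;
    sleep-opportunity/period durations -> Sleep Night; the remainder
    (efficiency, wakings, activity) -> Sleep Activity.  Requires variable
    columns named ``vNN_...`` (registry ids); unlabelled fits keep their
    PC column names.
    """
    from .core import Family, Window, registry_build

    reg = registry or registry_build()

    def vid(col: str) -> int | None:
        if isinstance(col, str) and col[:1] == "v" and col[1:3].isdigit():
            return int(col[1:3])
        return None

    votes: dict[str, dict[str, float]] = {}
    for var, (comp, _s) in solution.assignment.items():
        i = vid(var)
        if i is None:
            continue
        e = reg[i]
        w = abs(solution.loadings.loc[var, comp])
        lab = None
        if e.is_variability:
            lab = "Sleep Variability"
        elif e.family == Family.CLOCK_TIME:
            lab = "Sleep Timing"
        elif e.window in (Window.DAY, Window.CLOCK_DAY) or i == 44:
            lab = "Sleep Day"
        elif i in (13, 15, 17, 42):
            lab = "Sleep Night"
        else:
            lab = "Sleep Activity"
        votes.setdefault(comp, {}).setdefault(lab, 0.0)
        votes[comp][lab] += w

    labels: dict[str, str] = {}
    used: set[str] = set()
    # greedy: strongest vote first, each name used once
    flat = sorted(((w, comp, lab) for comp, d in votes.items()
                   for lab, w in d.items()), reverse=True)
    for w, comp, lab in flat:
        if comp in labels or lab in used:
            continue
        labels[comp] = lab
        used.add(lab)
    for comp in solution.loadings.columns:
        labels.setdefault(comp, comp)
    solution.component_labels = labels

    # canonical orientation: each composite points in its interpreted
    # direction (larger Sleep Day = more daytime sleep, larger Sleep
    # Activity = more nocturnal wake, ...), anchored on a marker variable
    markers = {"Sleep Activity": 21, "Sleep Variability": 14,
               "Sleep Day": 34, "Sleep Timing": 9, "Sleep Night": 15}
    col_of = {vid(c): c for c in solution.loadings.index}
    for comp, lab in labels.items():
        marker_col = col_of.get(markers.get(lab))
        if marker_col is None:
            continue
        if solution.loadings.loc[marker_col, comp] < 0:
            solution.loadings[comp] = -solution.loadings[comp]
            if solution.phi is not None:
                solution.phi.loc[comp, :] = -solution.phi.loc[comp, :]
                solution.phi.loc[:, comp] = -solution.phi.loc[:, comp]
            for var, (c, s) in list(solution.assignment.items()):
                if c == comp:
                    solution.assignment[var] = (c, -s)
    return solution


def score_composites(matrix: pd.DataFrame, solution: CompositeSolution
                     ) -> pd.DataFrame:
    """Per-assessment composite scores.

    Each composite is the unweighted mean over its assigned variables of
    the pooled z-score multiplied by the assignment sign, so the
    composite keeps its interpreted direction regardless of how its
    variables are oriented.  Raises on missing input (impute first).
    """
    cols = solution.retained
    x = matrix[cols]
    if x.isna().any().any():
        raise ValueError("score_composites requires complete data; impute first")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    out = {}
    for comp in solution.loadings.columns:
        members = solution.members(comp)
        signs = np.array([solution.assignment[v][1] for v in members])
        name = solution.component_labels.get(comp, comp)
        out[name] = (z[members] * signs).mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool_over_imputations(estimates: np.ndarray,
                          variances: np.ndarray | None = None) -> dict:
    """Pool an estimate over m imputations by Rubin's rules.

    ``estimates`` (m,) per-imputation point estimates; ``variances`` (m,)
    their squared standard errors (within-imputation variances).  Returns
    pooled estimate, total variance, between/within components and the
    adjusted degrees of freedom.  With m=1 the estimate passes through
    (with a warning) and the total variance is the within variance.
    """
    q = np.asarray(estimates, dtype=float)
    m = q.size
    w = (np.zeros(m) if variances is None
         else np.asarray(variances, dtype=float))
    qbar = q.mean()
    wbar = w.mean()
    if m == 1:
        warnings.warn("pooling a single imputation: passthrough", stacklevel=2)
        return {"estimate": float(qbar), "variance": float(wbar),
                "between": 0.0, "within": float(wbar), "df": np.inf, "m": 1}
    b = q.var(ddof=1)
    t = wbar + (1 + 1 / m) * b
    if b > 0 and t > 0:
        r = (1 + 1 / m) * b / wbar if wbar > 0 else np.inf
        df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1
    else:
        df = np.inf
    return {"estimate": float(qbar), "variance": float(t),
            "between": float(b), "within": float(wbar),
            "df": float(df), "m": m}
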