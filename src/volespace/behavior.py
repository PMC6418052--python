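"""Behavioral-type scoring from the combined dark-light / open-field test.

Workflow: score raw test observations into the assay variables, estimate
per-variable repeatability (intraclass correlation from a random-intercept
mixed model), invert latencies so that larger = bolder/faster, reduce the
repeatable variables with a principal component analysis under oblique
(oblimin) rotation, and extract one score per individual and component as
the conditional mode (BLUP) of a mixed model with the within-individual
centered test day as fixed effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

CENSOR_S = 300.0
N_SECTIONS = 16
N_SCANS = 30

EXPLORATION_ANCHORS = (
    "latency_middle_s",
    "sections_entered",
    "middle_crossings",
    "activity_prop",
)
BOLDNESS_ANCHORS = ("latency_head_s", "latency_body_s")


# ---------------------------------------------------------------------------
# test scoring


def score_test(raw_events, individual_id=None, round_=None, test_day=None) -> dict:
    """Score one raw event log into the assay variables.

    ``raw_events`` is a sequence of ``(time_s, kind, value)`` tuples.
    ``head_out`` / ``body_out`` times run from the start of the dark-light
    phase; arena events (``enter_middle``, ``enter_section`` with the
    section number, ``jump``, ``activity_scan`` with an active flag) run
    from full-body emergence.  Latencies without an event are censored at
    300 s; arena events after 300 s are ignored with a warning.
    """
    head = body = middle = None
    sections: set = set()
    crossings = jumps = 0
    scans: list = []
    late = 0
    for t, kind, value in ((e[0], e[1], e[2] if len(e) > 2 else None) for e in raw_events):
        if kind in ("head_out", "body_out"):
            if kind == "head_out" and head is None:
                head = min(t, CENSOR_S)
            if kind == "body_out" and body is None:
                body = min(t, CENSOR_S)
            continue
        if t > CENSOR_S:
            late += 1
            continue
        if kind == "enter_middle":
            crossings += 1
            if middle is None:
                middle = t
        elif kind == "enter_section":
            sections.add(int(value))
        elif kind == "jump":
            jumps += 1
        elif kind == "activity_scan":
            scans.append(bool(value))
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    if late:
        warnings.warn(f"{late} arena events after {CENSOR_S:.0f} s ignored")
    if len(scans) != N_SCANS:
        raise ValueError(f"expected {N_SCANS} activity scans, got {len(scans)}")
    if not sections <= set(range(1, N_SECTIONS + 1)):
        raise ValueError("section numbers must be in 1..16")
    rec = {
        "latency_head_s": head if head is not None else CENSOR_S,
        "latency_body_s": body if body is not None else CENSOR_S,
        "latency_middle_s": middle if middle is not None else CENSOR_S,
        "sections_entered": len(sections),
        "middle_crossings": crossings,
        "jumps": jumps,
        "activity_scans": "".join("1" if b else "0" for b in scans),
        "activity_prop": float(np.mean(scans)),
    }
    if individual_id is not None:
        rec["individual_id"] = individual_id
    if round_ is not None:
        rec["round"] = round_
    if test_day is not None:
        rec["test_day"] = test_day
    return rec


def invert_latencies(
    records: pd.DataFrame, columns=None, mode: str = "negate"
) -> pd.DataFrame:
    """Flip latency direction so that larger values mean faster animals.

    ``negate`` (default) preserves spacing exactly; ``reflect`` maps to
    ``300 - latency``, keeping values non-negative.  Both reverse the rank
    order, and applying the same mode twice restores the input (up to the
    reflect offset).
    """
    out = records.copy()
    if columns is None:
        columns = [c for c in out.columns if c.startswith("latency_")]
    for c in columns:
        if mode == "negate":
            out[c] = -out[c]
        elif mode == "reflect":
            out[c] = CENSOR_S - out[c]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# repeatability (intraclass correlation sensu variance partitioning)


@dataclass
class RepeatabilityResult:
    R: float
    SE: float
    CI_low: float
    CI_high: float
    p: float
    var_individual: float
    var_residual: float
    n_individuals: int
    n_obs: int


def _oneway_profiles(values: np.ndarray, ids: np.ndarray):
    """Group sufficient statistics for the one-way random-intercept model."""
    order = np.argsort(ids, kind="stable")
    v, g = values[order], ids[order]
    _, start = np.unique(g, return_index=True)
    groups = np.split(v, start[1:])
    n_i = np.array([len(x) for x in groups], float)
    means = np.array([x.mean() for x in groups])
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    return n_i, means, ss_within


def _neg_restricted_ll(lam, n_i, means, ss_within, N):
    w = n_i / (1.0 + n_i * lam)
    mu = (w * means).sum() / w.sum()
    q = ss_within + (w * (means - mu) ** 2).sum()
    return 0.5 * (
        (N - 1) * np.log(q) + np.log1p(n_i * lam).sum() + np.log(w.sum())
    )


def _ml_loglik(lam, n_i, means, ss_within, N):
    w = n_i / (1.0 + n_i * lam)
    mu = (w * means).sum() / w.sum()
    q = ss_within + (w * (means - mu) ** 2).sum()
    s2 = q / N
    return -0.5 * (N * np.log(2 * np.pi * s2) + np.log1p(n_i * lam).sum() + N)


def _fit_oneway_reml(values: np.ndarray, ids: np.ndarray):
    """Profiled REML for y_ij = mu + a_i + e_ij; returns (Vind, Vres).

    The restricted likelihood is profiled down to the single variance
    ratio lambda = Vind/Vres and maximized by bounded scalar search; on
    balanced designs the optimum coincides with the classical ANOVA
    estimator.
    """
    N = len(values)
    n_i, means, ss_within = _oneway_profiles(values, ids)
    if (n_i < 2).all():
        raise ValueError("repeatability undefined: no individual has 2 observations")
    res = optimize.minimize_scalar(
        _neg_restricted_ll,
        bounds=(0.0, 1e3),
        args=(n_i, means, ss_within, N),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = max(res.x, 0.0)
    if _neg_restricted_ll(0.0, n_i, means, ss_within, N) <= res.fun:
        lam = 0.0
    w = n_i / (1.0 + n_i * lam)
    mu = (w * means).sum() / w.sum()
    q = ss_within + (w * (means - mu) ** 2).sum()
    vres = q / (N - 1)
    return lam * vres, vres


def repeatability(
    values,
    individual_ids,
    n_boot: int = 1000,
    seed: int = 0,
    conf: float = 0.95,
) -> RepeatabilityResult:
    """Repeatability R = Vind / (Vind + Vres) from REML variance components.

    The p-value tests Vind = 0 by a likelihood-ratio test against the
    boundary-corrected null 0.5*chi2_0 + 0.5*chi2_1.  SE and the CI come
    from a parametric bootstrap of the fitted model (``n_boot`` refits;
    set 0 to skip).
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(individual_ids)
    if values.shape != ids.shape:
        raise ValueError("values and individual_ids must have the same length")
    keep = np.isfinite(values)
    values, ids = values[keep], ids[keep]

    uniq, counts = np.unique(ids, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError("repeatability undefined: need >=2 individuals with >=2 rounds")

    vind, vres = _fit_oneway_reml(values, ids)
    R = float(np.clip(vind / (vind + vres), 0.0, 1.0))

    # boundary-corrected LRT on the ML likelihoods
    N = len(values)
    n_i, means, ss_within = _oneway_profiles(values, ids)
    res = optimize.minimize_scalar(
        lambda lam: -_ml_loglik(lam, n_i, means, ss_within, N),
        bounds=(0.0, 1e3),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ll1 = max(-res.fun, _ml_loglik(0.0, n_i, means, ss_within, N))
    ll0 = _ml_loglik(0.0, n_i, means, ss_within, N)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = 1.0 if lrt == 0 else 0.5 * stats.chi2.sf(lrt, 1)

    se = ci_low = ci_high = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sizes = {u: c for u, c in zip(uniq, counts)}
        boot = np.empty(n_boot)
        idx = np.concatenate([[u] * sizes[u] for u in uniq])
        g = np.searchsorted(uniq, idx)
        for b in range(n_boot):
            a = rng.normal(0.0, np.sqrt(max(vind, 0.0)), len(uniq))
            y = a[g] + rng.normal(0.0, np.sqrt(vres), len(idx))
            bv, br = _fit_oneway_reml(y, idx)
            boot[b] = np.clip(bv / (bv + br), 0.0, 1.0)
        se = float(boot.std(ddof=1))
        alpha = 1.0 - conf
        ci_low, ci_high = np.quantile(boot, [alpha / 2, 1 - alpha / 2])

    return RepeatabilityResult(
        R=R,
        SE=se,
        CI_low=float(ci_low),
        CI_high=float(ci_high),
        p=float(p),
        var_individual=float(vind),
        var_residual=float(vres),
        n_individuals=len(uniq),
        n_obs=int(N),
    )


# ---------------------------------------------------------------------------
# PCA suitability diagnostics


def pca_suitability(data: pd.DataFrame) -> dict:
    """Determinant of the correlation matrix, Bartlett sphericity, KMO."""
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant columns are not allowed")
    R = np.corrcoef(X, rowvar=False)
    det = float(np.linalg.det(R))
    det = max(det, 0.0)

    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det) if det > 0 else np.inf
    df = p * (p - 1) // 2
    bartlett_p = float(stats.chi2.sf(chi2, df))

    off = ~np.eye(p, dtype=bool)
    if det < 1e-12:
        kmo = np.nan  # partial correlations undefined on a singular matrix
    else:
        Rinv = np.linalg.inv(R)
        d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
        partial = -Rinv / d
        kmo = float((R[off] ** 2).sum() / ((R[off] ** 2).sum() + (partial[off] ** 2).sum()))
    return {
        "determinant": det,
        "bartlett_chi2": float(chi2),
        "bartlett_df": int(df),
        "bartlett_p": bartlett_p,
        "KMO": kmo,
    }


# ---------------------------------------------------------------------------
# PCA with oblimin rotation


def _quartimin_objective(L: np.ndarray):
    L2 = L**2
    Nmat = 1.0 - np.eye(L.shape[1])
    X = L2 @ Nmat
    return (L2 * X).sum() / 4.0, L * X


def _oblimin_rotate(A: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """Direct-quartimin (oblimin, gamma = 0) rotation by gradient projection.

    Returns (pattern, phi) with ``pattern = A @ inv(T).T`` and factor
    correlation ``phi = T.T @ T``.
    """
    k = A.shape[1]
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_objective(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            Tt = X / np.sqrt((X**2).sum(axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin_objective(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # rotated pattern matrix (variables x components)
    structure: pd.DataFrame         # pattern @ phi
    phi: np.ndarray                 # component correlations
    eigenvalues: np.ndarray         # all eigenvalues of the correlation matrix
    explained_variance: np.ndarray  # pre-rotation fraction per retained component
    scores: pd.DataFrame            # regression-method component scores per row
    n_retained: int
    communalities: pd.Series = field(default=None)


def pca_oblimin(
    data: pd.DataFrame,
    sign_anchors: dict | None = None,
    eigenvalue_threshold: float = 1.0,
) -> PCAResult:
    """PCA on the correlation matrix, retaining eigenvalue > 1 components,
    with oblique (direct quartimin) rotation and regression-method scores.

    ``sign_anchors`` maps a component label to variable names; each
    retained component is assigned the label whose anchor variables it
    loads most strongly, and its sign is flipped so those loadings are
    positive.  With the assay anchors this enforces: more crossings /
    sections / activity = higher exploration, faster emergence (larger
    inverted latency) = higher boldness.
    """
    cols = list(data.columns)
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    k = int((evals > eigenvalue_threshold).sum())
    if k == 0:
        raise ValueError("no component with eigenvalue above threshold")
    A = evecs[:, :k] * np.sqrt(evals[:k])

    if k == 1:
        warnings.warn("single retained component; rotation skipped")
        pattern, phi = A.copy(), np.eye(1)
    else:
        pattern, phi = _oblimin_rotate(A)

    labels = [f"PC{j + 1}" for j in range(k)]
    # order rotated components by explained sum of squared structure loadings
    structure = pattern @ phi
    ss = (structure**2).sum(axis=0)
    comp_order = np.argsort(ss)[::-1]
    pattern, structure = pattern[:, comp_order], structure[:, comp_order]
    phi = phi[np.ix_(comp_order, comp_order)]

    if sign_anchors:
        assigned = {}
        for j in range(k):
            best, best_val = None, -np.inf
            for label, anchors in sign_anchors.items():
                ix = [cols.index(a) for a in anchors if a in cols]
                if not ix:
                    continue
                val = np.abs(pattern[ix, j]).mean()
                if label not in assigned.values() and val > best_val:
                    best, best_val = label, val
            if best is not None:
                assigned[j] = best
        new_labels = [assigned.get(j, labels[j]) for j in range(k)]
        for j in range(k):
            label = assigned.get(j)
            if label is None:
                continue
            ix = [cols.index(a) for a in sign_anchors[label] if a in cols]
            if pattern[ix, j].mean() < 0:
                pattern[:, j] *= -1
                structure[:, j] *= -1
                phi[j, :] *= -1
                phi[:, j] *= -1
        labels = new_labels
    else:
        for j in range(k):
            i = int(np.argmax(np.abs(pattern[:, j])))
            if pattern[i, j] < 0:
                pattern[:, j] *= -1
                structure[:, j] *= -1
                phi[j, :] *= -1
                phi[:, j] *= -1

    weights = np.linalg.solve(R, structure)
    scores = Z @ weights

    return PCAResult(
        loadings=pd.DataFrame(pattern, index=cols, columns=labels),
        structure=pd.DataFrame(structure, index=cols, columns=labels),
        phi=phi,
        eigenvalues=evals,
        explained_variance=evals[:k] / p,
        scores=pd.DataFrame(scores, columns=labels, index=data.index),
        n_retained=k,
        communalities=pd.Series((A**2).sum(axis=1), index=cols),
    )


# ---------------------------------------------------------------------------
# per-individual scores (conditional modes)


def blup_scores(
    component_scores: pd.DataFrame,
    test_day,
    individual_ids,
) -> pd.DataFrame:
    """Shrinkage scores per individual: conditional modes of a mixed model
    with within-individual centered test day as fixed effect.

    Centering the day within individuals removes between-individual
    differences in testing schedule, so adding a constant to every test
    day leaves the scores unchanged.
    """
    import statsmodels.api as sm

    ids = np.asarray(individual_ids)
    day = np.asarray(test_day, dtype=float)
    uniq, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
    if (counts >= 2).mean() < 0.8:
        raise ValueError("need >=2 rounds for at least 80% of individuals")
    day_mean = np.bincount(inv, weights=day) / counts
    day_c = day - day_mean[inv]

    out = {}
    X = np.column_stack([np.ones_like(day_c), day_c])
    for comp in component_scores.columns:
        y = np.asarray(component_scores[comp], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=ids).fit(reml=True)
        if not np.isfinite(fit.params).all():
            raise RuntimeError(
                f"mixed model for {comp} failed to converge; "
                f"variance components: cov_re={np.asarray(fit.cov_re)}, scale={fit.scale}"
            )
        modes = {g: float(np.asarray(re).ravel()[0]) for g, re in fit.random_effects.items()}
        out[comp] = [modes[u] for u in uniq]
    return pd.DataFrame(out, index=pd.Index(uniq, name="individual_id"))


# ---------------------------------------------------------------------------
# rank correlation


def spearman(x, y) -> dict:
    """Spearman rank correlation with average ranks for ties.

    Returns ``rho`` (tie-corrected, the Pearson correlation of the ranks),
    the classical statistic ``S = sum of squared rank differences``, and
    the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    S = float(((rx - ry) ** 2).sum())
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = float(stats.spearmanr(x, y).pvalue)
    return {"rho": rho, "S": S, "p": p}
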