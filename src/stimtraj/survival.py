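"""Cox proportional-hazards comparison of treatment subgroups with family clustering.

Survival construction follows the study design exactly: for each outcome
domain (SUD, daily smoking, nicotine dependence) cases contribute age at
first substance / nicotine use as the event time, non-cases contribute age at
follow-up as censoring time; the time scale is age with entry at 0.

The partial likelihood is maximized by Newton-Raphson with Breslow handling
of ties (Efron available). Sibling dependence is corrected with the Lin-Wei
robust (sandwich) covariance, summing score residuals within families:

    V_robust = I^-1 (sum_c s_c s_c') I^-1,   s_c = sum_{i in c} U_i,

where U_i are the per-subject score residuals and I the observed information.
Hazard ratios, their 95% CIs and Wald tests all use the robust covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ConvergenceError, DataError, DegenerateDataError
from .io import STIMULANT_CLASSES, OutcomeRecord, SubjectRecord

DOMAINS = ("sud", "daily_smoking", "nicotine_dependence")

_DOMAIN_FIELDS = {
    "sud": ("sud", "age_first_substance_use"),
    "daily_smoking": ("daily_smoking", "age_first_nicotine_use"),
    "nicotine_dependence": ("nicotine_dependence", "age_first_nicotine_use"),
}

MAX_ITER = 100
LOGLIK_TOL = 1e-9
BETA_BOUND = 50.0  # |beta| beyond this signals monotone likelihood


def non_stimulant_users(prescriptions) -> set[str]:
    """Subjects with at least one non-stimulant dispense (sensitivity covariate)."""
    return {
        r.subject_id for r in prescriptions if r.drug_class not in STIMULANT_CLASSES
    }


def make_survival_dataset(
    subjects: list[SubjectRecord],
    outcomes: list[OutcomeRecord],
    groups: dict[str, str],
    domain: str,
    non_stimulant_ids: set[str] | None = None,
) -> pd.DataFrame:
    """One row per grouped subject: time, event, group, covariates."""
    if domain not in _DOMAIN_FIELDS:
        raise DataError(f"unknown outcome domain {domain!r}; expected one of {DOMAINS}")
    flag_field, age_field = _DOMAIN_FIELDS[domain]
    out_by_id = {o.subject_id: o for o in outcomes}
    rows = []
    bad: list[str] = []
    for s in subjects:
        if s.subject_id not in groups:
            continue
        try:
            o = out_by_id[s.subject_id]
        except KeyError:
            raise DataError(f"subject {s.subject_id} has no outcome record") from None
        is_case = getattr(o, flag_field)
        if is_case:
            t = getattr(o, age_field)
            if t is None or t >= s.age_at_followup:
                bad.append(s.subject_id)
                continue
        else:
            t = s.age_at_followup
        rows.append(
            {
                "subject_id": s.subject_id,
                "family_id": s.family_id,
                "time": float(t),
                "event": int(is_case),
                "group": groups[s.subject_id],
                "ses": s.ses,
                "iq": s.iq,
                "cd": int(s.cd),
                "adhd_severity": s.hyperactive_symptoms + s.inattentive_symptoms,
                "non_stimulant_use": int(
                    s.subject_id in non_stimulant_ids
                ) if non_stimulant_ids is not None else 0,
            }
        )
    if bad:
        raise ConsistencyError(
            f"{domain}: case(s) with missing or post-follow-up first-use age: {bad}"
        )
    cols = [
        "subject_id", "family_id", "time", "event", "group",
        "ses", "iq", "cd", "adhd_severity", "non_stimulant_use",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_clusters: int
    ties: str
    group_labels: list[str]  # all groups including the reference
    reference_group: str
    group_terms: list[str]  # dummy-term names, aligned with group_labels[1:]
    baseline_times: np.ndarray  # distinct event times, ascending
    baseline_increments: np.ndarray  # Breslow dLambda0 at each event time

    def term_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DataError(f"unknown model term {name!r}") from None

    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def summary(self) -> pd.DataFrame:
        se = self.robust_se()
        z = self.beta / se
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": np.exp(self.beta),
                "robust_se": se,
                "hr_ci_low": np.exp(self.beta - 1.959963984540054 * se),
                "hr_ci_high": np.exp(self.beta + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.names,
        )

    def _group_coef_vector(self, label: str) -> np.ndarray:
        """Coefficient-space representation of a group (reference = zero vector)."""
        if label not in self.group_labels:
            raise DataError(f"unknown group {label!r}")
        v = np.zeros(len(self.names))
        if label != self.reference_group:
            v[self.term_index(f"group[{label}]")] = 1.0
        return v


def _design(
    data: pd.DataFrame,
    group_col: str,
    reference_group: str | None,
    covariates: list[str],
) -> tuple[np.ndarray, list[str], list[str], str, list[str]]:
    labels = sorted(data[group_col].astype(str).unique())
    if reference_group is None:
        reference_group = labels[0]
    if reference_group not in labels:
        raise DataError(f"reference group {reference_group!r} not present in data")
    dummy_labels = [g for g in labels if g != reference_group]
    names = [f"group[{g}]" for g in dummy_labels] + list(covariates)
    cols = [
        (data[group_col].astype(str) == g).to_numpy(float) for g in dummy_labels
    ] + [data[c].to_numpy(float) for c in covariates]
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names, labels, reference_group, [f"group[{g}]" for g in dummy_labels]


def _partial_loglik(beta, t, d, X, ties):
    """Log partial likelihood, gradient, Hessian and risk-set sums.

    Arrays must be sorted by ascending time. Returns (ll, grad, hess,
    s0_first, first_idx) where s0_first[i] is S0 at the tie-group-first
    position of sorted index i.
    """
    n, p = X.shape
    eta = X @ beta
    e = np.exp(eta)
    # reverse (suffix) cumulative sums over the risk sets
    s0 = np.cumsum(e[::-1])[::-1]
    s1 = np.cumsum((X * e[:, None])[::-1], axis=0)[::-1]
    s2 = np.cumsum((X[:, :, None] * X[:, None, :] * e[:, None, None])[::-1], axis=0)[::-1]
    first_idx = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(d == 1)
    if ties == "breslow":
        fi = first_idx[ev]
        ll = float(eta[ev].sum() - np.log(s0[fi]).sum())
        xbar = s1[fi] / s0[fi][:, None]
        grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
        hess = np.zeros((p, p))
        for j, i0 in enumerate(fi):
            v = s1[i0] / s0[i0]
            hess -= s2[i0] / s0[i0] - np.outer(v, v)
    else:  # efron
        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0)
        hess = np.zeros((p, p))
        # iterate over tie groups of events
        groups: dict[int, list[int]] = {}
        for i in ev:
            groups.setdefault(first_idx[i], []).append(i)
        for i0, members in groups.items():
            dsize = len(members)
            e0 = e[members].sum()
            e1 = (X[members] * e[members, None]).sum(axis=0)
            e2 = (
                X[members][:, :, None] * X[members][:, None, :] * e[members, None, None]
            ).sum(axis=0)
            for r in range(dsize):
                f = r / dsize
                a0 = s0[i0] - f * e0
                a1 = s1[i0] - f * e1
                a2 = s2[i0] - f * e2
                ll -= np.log(a0)
                v = a1 / a0
                grad -= v
                hess -= a2 / a0 - np.outer(v, v)
    return ll, grad, hess, s0, first_idx


def _score_residuals(t, d, X, beta, s0, first_idx):
    """Per-subject score residuals (Breslow form), sorted order."""
    n, p = X.shape
    e = np.exp(X @ beta)
    ev = np.flatnonzero(d == 1)
    fi = first_idx[ev]
    ev_times = t[ev]
    inc0 = 1.0 / s0[fi]
    s1 = np.cumsum((X * e[:, None])[::-1], axis=0)[::-1]
    xbar_ev = s1[fi] / s0[fi][:, None]
    inc1 = xbar_ev * inc0[:, None]
    c0 = np.concatenate([[0.0], np.cumsum(inc0)])
    c1 = np.vstack([np.zeros(p), np.cumsum(inc1, axis=0)])
    pos = np.searchsorted(ev_times, t, side="right")
    U = -e[:, None] * (X * c0[pos][:, None] - c1[pos])
    U[ev] += X[ev] - xbar_ev
    return U


def fit_cox(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
    reference_group: str | None = None,
    covariates: list[str] | None = None,
    cluster_col: str | None = "family_id",
    ties: str = "breslow",
) -> CoxFit:
    """Maximize the Cox partial likelihood and attach the cluster-robust covariance."""
    covariates = list(covariates or [])
    if ties not in ("breslow", "efron"):
        raise DataError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if len(data) == 0:
        raise DegenerateDataError("empty survival dataset")
    X, names, labels, reference_group, group_terms = _design(
        data, group_col, reference_group, covariates
    )
    t = data[duration_col].to_numpy(float)
    d = data[event_col].to_numpy(int)
    if np.any(t <= 0):
        raise DataError("survival times must be positive")
    if d.sum() == 0:
        raise DegenerateDataError("no events in the dataset")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateDataError(f"term {name!r} is constant across subjects")

    order = np.argsort(t, kind="stable")
    t_s, d_s, X_s = t[order], d[order], X[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess, s0, first_idx = _partial_loglik(beta, t_s, d_s, X_s, ties)
    for _ in range(MAX_ITER):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta + step
        new = _partial_loglik(new_beta, t_s, d_s, X_s, ties)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _partial_loglik(new_beta, t_s, d_s, X_s, ties)
            halvings += 1
        delta = new[0] - ll
        beta = new_beta
        ll, grad, hess, s0, first_idx = new
        if np.any(np.abs(beta) > BETA_BOUND):
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone partial likelihood (complete separation) in term {worst!r}"
            )
        if abs(delta) < LOGLIK_TOL:
            break
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {MAX_ITER} iterations")

    info = -hess
    cov_model = np.linalg.inv(info)

    U = _score_residuals(t_s, d_s, X_s, beta, s0, first_idx)
    if cluster_col is not None and cluster_col in data.columns:
        clusters = data[cluster_col].to_numpy()[order]
    else:
        clusters = np.arange(len(data))
    _, inv = np.unique(clusters, return_inverse=True)
    n_clusters = int(inv.max()) + 1
    S = np.zeros((n_clusters, p))
    np.add.at(S, inv, U)
    cov_robust = cov_model @ (S.T @ S) @ cov_model

    # Breslow baseline cumulative hazard (covariates at zero)
    ev = np.flatnonzero(d_s == 1)
    fi = first_idx[ev]
    uniq_fi, counts = np.unique(fi, return_counts=True)
    baseline_times = t_s[uniq_fi]
    baseline_increments = counts / s0[uniq_fi]

    return CoxFit(
        names=names,
        beta=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        loglik=ll,
        n=len(data),
        n_events=int(d.sum()),
        n_clusters=n_clusters,
        ties=ties,
        group_labels=labels,
        reference_group=reference_group,
        group_terms=group_terms,
        baseline_times=baseline_times,
        baseline_increments=baseline_increments,
    )


def wald_group_test(fit: CoxFit, group_terms: list[str] | None = None):
    """Overall Wald chi-square that all group coefficients are zero (robust V)."""
    terms = group_terms if group_terms is not None else fit.group_terms
    if not terms:
        raise DataError("no group terms in the fit")
    idx = [fit.term_index(nm) for nm in terms]
    b = fit.beta[idx]
    V = fit.cov_robust[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("singular covariance block in Wald test") from exc
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def pairwise_hazard_ratios(
    fit: CoxFit, groups: list[str] | None = None, holm: bool = False
) -> pd.DataFrame:
    """HR, robust 95% CI and p for every ordered pair of groups.

    Each contrast is a linear combination of coefficients, so
    HR(a vs b) = 1 / HR(b vs a) holds exactly. ``holm`` applies a Holm
    adjustment over the unordered pairs (off by default, matching unadjusted
    pairwise reporting).
    """
    groups = list(groups or fit.group_labels)
    rows = []
    for a in groups:
        for b in groups:
            if a == b:
                continue
            c = fit._group_coef_vector(a) - fit._group_coef_vector(b)
            est = float(c @ fit.beta)
            var = float(c @ fit.cov_robust @ c)
            se = np.sqrt(var)
            z = est / se if se > 0 else 0.0
            rows.append(
                {
                    "group": a,
                    "versus": b,
                    "hr": float(np.exp(est)),
                    "ci_low": float(np.exp(est - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(est + 1.959963984540054 * se)),
                    "p": float(2 * stats.norm.sf(abs(z))),
                }
            )
    out = pd.DataFrame(rows)
    if holm:
        mask = out.apply(lambda r: r["group"] < r["versus"], axis=1)
        sub = out[mask].sort_values("p")
        m = len(sub)
        adj = np.minimum(np.maximum.accumulate(sub["p"].to_numpy() * np.arange(m, 0, -1)), 1.0)
        padj = dict(zip(map(tuple, sub[["group", "versus"]].values), adj))
        out["p_holm"] = [
            padj.get((r["group"], r["versus"]), padj.get((r["versus"], r["group"])))
            for _, r in out.iterrows()
        ]
    return out


def cumulative_incidence(fit: CoxFit, group: str) -> pd.DataFrame:
    """1 - S(t) for a group: Breslow baseline, scaled by exp(beta_group)."""
    v = fit._group_coef_vector(group)
    lam = np.cumsum(fit.baseline_increments) * float(np.exp(v @ fit.beta))
    times = np.concatenate([[0.0], fit.baseline_times])
    ci = np.concatenate([[0.0], 1.0 - np.exp(-lam)])
    return pd.DataFrame({"group": group, "time": times, "cumulative_incidence": ci})


@dataclass
class MatchResult:
    selected_ids: list[str]
    target_group: str  # smallest group, whose pooled mean anchors the matching
    balance: pd.DataFrame  # per variable: max pre/post standardized mean difference


def match_groups(
    subjects: list[SubjectRecord],
    groups: dict[str, str],
    variables: tuple[str, ...] = ("baseline_age", "hyperactive_symptoms"),
    target_n: int | None = None,
) -> MatchResult:
    """Select equal-sized subgroups balanced on the matching variables.

    Greedy nearest-neighbour selection without replacement: within each group
    the ``target_n`` subjects closest (Mahalanobis distance, pooled
    covariance) to the smallest group's mean vector are retained.
    """
    rows = [
        {"subject_id": s.subject_id, "group": groups[s.subject_id],
         **{v: float(getattr(s, v)) for v in variables}}
        for s in subjects
        if s.subject_id in groups
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("no grouped subjects to match")
    sizes = df.groupby("group").size()
    smallest = sizes.idxmin()
    if target_n is None:
        target_n = int(sizes.min())
    if target_n > sizes.min():
        raise DataError(
            f"target_n {target_n} exceeds smallest group size {int(sizes.min())}"
        )
    V = np.cov(df[list(variables)].to_numpy().T)
    V = np.atleast_2d(V)
    Vinv = np.linalg.pinv(V)
    target = df.loc[df["group"] == smallest, list(variables)].mean().to_numpy()

    selected = []
    for g, sub in df.groupby("group"):
        Xg = sub[list(variables)].to_numpy() - target
        dist = np.einsum("ij,jk,ik->i", Xg, Vinv, Xg)
        keep = sub.iloc[np.argsort(dist, kind="stable")[:target_n]]
        selected.extend(keep["subject_id"].tolist())

    # standardized mean differences; the denominator is always the
    # pre-matching pooled SD, the standard convention for judging balance
    def max_smd(frame: pd.DataFrame, var: str) -> float:
        denom = np.sqrt(df.groupby("group")[var].var().mean())
        if denom == 0:
            return 0.0
        means = frame.groupby("group")[var].mean()
        return float((means.max() - means.min()) / denom)

    post = df[df["subject_id"].isin(selected)]
    balance = pd.DataFrame(
        {
            "variable": list(variables),
            "pre_max_smd": [max_smd(df, v) for v in variables],
            "post_max_smd": [max_smd(post, v) for v in variables],
        }
    )
    return MatchResult(selected_ids=sorted(selected), target_group=smallest, balance=balance)
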