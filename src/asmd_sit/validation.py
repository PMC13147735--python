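"""Internal validation: bootstrap metrics and ROC analysis.

Performance of the suspicion index is assessed for the two published
contrasts — ASMD cases vs controls and cases vs non-cases — with fixed-cutoff
accuracy, sensitivity and specificity, and cutoff-free ROC curves whose AUC
uses the midrank tie convention (AUC equals the normalised two-sample
rank-sum statistic: the probability that a random case outscores a random
comparator, ties counted 1/2). Uncertainty comes from a stratified
nonparametric bootstrap: each repetition resamples patients with replacement
within group, refits the model on a 70% split of the resample and evaluates
on the remaining 30%; percentile confidence intervals are order statistics of
the repetition distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .cohort import Cohort
from .multinomial import CLASS_ORDER, fit_multinomial
from .sit import SITModel

CONTRASTS = ("case_vs_control", "case_vs_non_case")
_COMPARATOR = {"case_vs_control": "control", "case_vs_non_case": "non_case"}


@dataclass(frozen=True)
class ValidationConfig:
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    contrasts: tuple[str, ...] = CONTRASTS
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}")


def classification_metrics(scores, contrast: str, cutoff: float):
    """(accuracy, sensitivity, specificity) at a fixed cutoff.

    ``scores`` is an iterable of (probability_case, true_group) pairs; only
    the two groups of the contrast are used. A case is predicted when
    probability_case >= cutoff.
    """
    comparator = _COMPARATOR[contrast]
    s_case = [p for p, g in scores if g == "case"]
    s_comp = [p for p, g in scores if g == comparator]
    if not s_case or not s_comp:
        raise ValueError(f"contrast {contrast!r} needs both classes present")
    tp = sum(p >= cutoff for p in s_case)
    tn = sum(p < cutoff for p in s_comp)
    sens = tp / len(s_case)
    spec = tn / len(s_comp)
    acc = (tp + tn) / (len(s_case) + len(s_comp))
    return acc, sens, spec


def roc_curve(scores, contrast: str):
    """ROC points and AUC for one contrast.

    Returns (points, auc) where points is a list of (fpr, tpr, threshold)
    starting at (0,0) and ending at (1,1); thresholds sit at the unique score
    values. AUC is the trapezoidal area, equal under the midrank tie
    convention to the normalised concordance count.
    """
    comparator = _COMPARATOR[contrast]
    y, s = [], []
    for p, g in scores:
        if g == "case":
            y.append(1); s.append(p)
        elif g == comparator:
            y.append(0); s.append(p)
    if not any(y) or all(y):
        raise ValueError(f"contrast {contrast!r} needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())), auc


def _percentile_ci(values: np.ndarray, ci_level: float):
    """Percentile bootstrap interval as order statistics of the draws."""
    s = np.sort(np.asarray(values))
    b = len(s)
    alpha = 1.0 - ci_level
    # epsilon guards against float artifacts in alpha/2 * b landing just
    # above an integer (e.g. 0.025 * 200)
    lo = s[max(int(np.ceil(alpha / 2 * b - 1e-9)) - 1, 0)]
    hi = s[min(int(np.ceil((1 - alpha / 2) * b - 1e-9)) - 1, b - 1)]
    return float(lo), float(hi)


@dataclass
class ContrastReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    auc_ci: tuple[float, float]
    roc_points: list[tuple[float, float, float]]


@dataclass
class ValidationReport:
    config: ValidationConfig
    contrasts: dict[str, ContrastReport]
    redraws: int = 0

    def summary(self) -> str:
        lines = ["Bootstrap internal validation", "=" * 60]
        for name, r in self.contrasts.items():
            lines += [
                f"{name}:",
                f"  accuracy     {r.accuracy:6.3f}  CI [{r.accuracy_ci[0]:.3f}, {r.accuracy_ci[1]:.3f}]",
                f"  sensitivity  {r.sensitivity:6.3f}  CI [{r.sensitivity_ci[0]:.3f}, {r.sensitivity_ci[1]:.3f}]",
                f"  specificity  {r.specificity:6.3f}  CI [{r.specificity_ci[0]:.3f}, {r.specificity_ci[1]:.3f}]",
                f"  AUC          {r.auc:6.3f}  CI [{r.auc_ci[0]:.3f}, {r.auc_ci[1]:.3f}]",
            ]
        return "\n".join(lines)


def _scores_for(model_results, cohort_frame, variables):
    sub = cohort_frame[variables + ["group"]].dropna(subset=variables)
    if len(sub) == 0:
        return []
    probs = np.atleast_2d(model_results.predict_proba(sub[variables]))
    p_case = probs[:, CLASS_ORDER.index("case")]
    return list(zip(p_case.tolist(), sub["group"].tolist()))


def bootstrap_validate(model: SITModel, cohort: Cohort,
                       config: ValidationConfig | None = None) -> ValidationReport:
    """Stratified bootstrap validation of the suspicion index.

    Point estimates come from refitting on a 70/30 split of the original
    cohort (first repetition's split of the unresampled data); the CI comes
    from the bootstrap repetition distribution. Reproducible from the seed.
    """
    config = config or ValidationConfig()
    df = cohort.frame
    variables = list(model.model.spec.variables)
    y_groups = df["group"].to_numpy()
    group_idx = {g: np.where(y_groups == g)[0] for g in CLASS_ORDER}
    for contrast in config.contrasts:
        comparator = _COMPARATOR[contrast]
        if len(group_idx["case"]) == 0 or len(group_idx[comparator]) == 0:
            raise ValueError(f"cohort lacks a class for contrast {contrast!r}")

    root = np.random.SeedSequence(config.seed)
    spec = model.model.spec
    metrics: dict[str, dict[str, list[float]]] = {
        c: {"accuracy": [], "sensitivity": [], "specificity": [], "auc": []}
        for c in config.contrasts}
    redraws = 0
    rep = 0
    point: dict[str, tuple] = {}
    while rep < config.bootstrap_reps:
        rng = np.random.default_rng(root.spawn(1)[0])
        # stratified resample with replacement
        take = np.concatenate([
            rng.choice(idx, size=len(idx), replace=True)
            for g, idx in group_idx.items() if len(idx)])
        boot = df.iloc[take].reset_index(drop=True)
        # resampled charts are new pseudo-patients; keep ids unique
        boot["patient_id"] = [f"boot-{i:06d}" for i in range(len(boot))]
        yb = boot["group"].to_numpy()
        tr_mask = np.zeros(len(boot), dtype=bool)
        for g in np.unique(yb):
            gi = np.where(yb == g)[0]
            ntr = int(round(config.train_fraction * len(gi)))
            ntr = min(max(ntr, 1), len(gi) - 1) if len(gi) > 1 else len(gi)
            perm = rng.permutation(gi)
            tr_mask[perm[:ntr]] = True
        train, test = boot[tr_mask], boot[~tr_mask]
        if (len(set(train["group"])) < 3
                or any(len(test[test["group"] == g]) == 0
                       for g in ("case",) + tuple(
                           _COMPARATOR[c] for c in config.contrasts))):
            redraws += 1
            continue
        rep += 1
        fitted = fit_multinomial(
            Cohort(train.reset_index(drop=True), cohort.catalog), spec)
        test_scores = _scores_for(fitted, test, variables)
        ok = True
        vals = {}
        for contrast in config.contrasts:
            try:
                acc, sens, spc = classification_metrics(
                    test_scores, contrast, model.cutoff)
                _, auc = roc_curve(test_scores, contrast)
            except ValueError:
                ok = False
                break
            vals[contrast] = (acc, sens, spc, auc)
        if not ok:
            rep -= 1
            redraws += 1
            continue
        for contrast, (acc, sens, spc, auc) in vals.items():
            m = metrics[contrast]
            m["accuracy"].append(acc)
            m["sensitivity"].append(sens)
            m["specificity"].append(spc)
            m["auc"].append(auc)

    # point estimate and ROC on the full cohort with the supplied model
    full_scores = _scores_for(model.model, df, variables)
    contrasts_out = {}
    for contrast in config.contrasts:
        acc, sens, spc = classification_metrics(full_scores, contrast, model.cutoff)
        points, auc = roc_curve(full_scores, contrast)
        m = metrics[contrast]
        contrasts_out[contrast] = ContrastReport(
            accuracy=acc, sensitivity=sens, specificity=spc, auc=auc,
            accuracy_ci=_percentile_ci(np.array(m["accuracy"]), config.ci_level),
            sensitivity_ci=_percentile_ci(np.array(m["sensitivity"]), config.ci_level),
            specificity_ci=_percentile_ci(np.array(m["specificity"]), config.ci_level),
            auc_ci=_percentile_ci(np.array(m["auc"]), config.ci_level),
            roc_points=points,
        )
    return ValidationReport(config=config, contrasts=contrasts_out, redraws=redraws)


def plot_roc(report: ValidationReport, path) -> None:
    """Write a ROC figure (one curve per contrast) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in report.contrasts.items():
        fpr = [p[0] for p in r.roc_points]
        tpr = [p[1] for p in r.roc_points]
        ax.plot(fpr, tpr, label=f"{name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
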