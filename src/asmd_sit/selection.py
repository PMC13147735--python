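"""Resampled best-subset stability selection of model variables.

The published workflow caps model size with the events-per-variable (EPV)
rule — at least 10 events (here: ASMD cases) per predictor, so 48 cases
admit at most four variables — and then repeats, over many random 70/30
train/test splits, an exhaustive search over all variable subsets up to that
cap, fitting the multinomial model on the training split and scoring it on
the test split. Variables appearing in more than 70% of the per-repetition
winning subsets form the final set. A random-forest importance ranking
(mean decrease in impurity, averaged over repetitions) provides an
independent cross-check of the same candidate list.

Hepatomegaly and splenomegaly are merged into a single
``hepatosplenomegaly`` variable before enumeration (their co-occurrence in
ASMD makes them nearly redundant, and the merged sign is the deployed tool's
prerequisite), so the four-variable cap covers the tool's five named signs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .catalog import SymptomEntry
from .cohort import Cohort
from .multinomial import CLASS_ORDER, _newton_fit, _softmax_probs

logger = logging.getLogger(__name__)

CRITERIA = ("test_accuracy", "test_deviance")


def max_subset_size_from_epv(n_events: int, epv: int = 10) -> int:
    """Largest admissible model size under the events-per-variable rule."""
    if n_events < epv:
        raise ValueError(
            f"no admissible model: {n_events} events < {epv} required per variable")
    return n_events // epv


def merge_hepatosplenomegaly(cohort: Cohort, rule: str = "and",
                             source_a: str = "hepatomegaly",
                             source_b: str = "splenomegaly",
                             name: str = "hepatosplenomegaly") -> Cohort:
    """Add a combined liver+spleen enlargement variable to the cohort.

    Under the default ``and`` rule the merged sign is present iff both
    sources are present; an undecidable conjunction (one source unknown, the
    other not absent) stays unknown. ``rule="or"`` marks it present if either
    source is present. Source columns are retained.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    cat = cohort.catalog
    if name in cat:
        raise ValueError(f"variable {name!r} already exists in the catalog")
    for src in (source_a, source_b):
        if src not in cat:
            raise ValueError(f"source symptom {src!r} not in catalog")
    df = cohort.frame.copy()
    # Kleene three-valued logic: absent & anything = absent, present | anything
    # = present; undecidable conjunctions/disjunctions stay unknown
    a = df[source_a].astype("boolean")
    b = df[source_b].astype("boolean")
    merged = (a & b) if rule == "and" else (a | b)
    df[name] = merged.astype("Int8")
    new_cat = cat.with_entry(
        SymptomEntry(name, "Hepatosplenomegaly", cat.organ_system(source_a)),
        after=source_b,
    )
    return Cohort(df, new_cat)


@dataclass(frozen=True)
class SelectionConfig:
    candidate_variables: tuple[str, ...]
    repetitions: int = 1000
    train_fraction: float = 0.70
    epv: int = 10
    max_subset_size: int | None = None  # None = derive from EPV rule
    criterion: str = "test_accuracy"
    frequency_threshold: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.candidate_variables:
            raise ValueError("candidate set must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0 < self.frequency_threshold < 1:
            raise ValueError("frequency_threshold must be in (0,1)")
        if self.max_subset_size is not None and self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")


@dataclass
class SelectionReport:
    config: SelectionConfig
    max_subset_size: int
    per_rep_winners: list[tuple[str, ...]]
    per_rep_criterion: list[float]
    occurrence_frequency: dict[str, float]
    final_set: tuple[str, ...]
    redraws: int = 0

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.occurrence_frequency.items(), key=lambda kv: -kv[1]),
            columns=["symptom_id", "frequency"],
        )

    def summary(self) -> str:
        lines = [
            "Best-subset stability selection",
            "=" * 46,
            f"candidates:     {len(self.config.candidate_variables)}",
            f"repetitions:    {len(self.per_rep_winners)}",
            f"max subset:     {self.max_subset_size} (EPV >= {self.config.epv})",
            f"criterion:      {self.config.criterion}",
            "-" * 46,
        ]
        for sid, f in sorted(self.occurrence_frequency.items(), key=lambda kv: -kv[1]):
            mark = " *" if sid in self.final_set else ""
            lines.append(f"  {sid:<36s}{f:6.2f}{mark}")
        lines.append("-" * 46)
        lines.append(f"final set (> {self.config.frequency_threshold:.0%}): "
                     + ", ".join(self.final_set))
        return "\n".join(lines)


def _stratified_split(rng, y, train_fraction):
    """Boolean train mask, stratified by class; sizes deterministic."""
    mask = np.zeros(len(y), dtype=bool)
    for g in np.unique(y):
        idx = np.where(y == g)[0]
        ntr = int(round(train_fraction * len(idx)))
        ntr = min(max(ntr, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        perm = rng.permutation(idx)
        mask[perm[:ntr]] = True
    return mask


def best_subset_select(cohort: Cohort, config: SelectionConfig) -> SelectionReport:
    """Exhaustive best-subset search over repeated stratified splits.

    Per repetition the winner is the subset with the best test criterion;
    ties are broken toward smaller subsets, then lexicographically on sorted
    variable names. The subset enumeration is exact (no heuristic search):
    with <= 12 candidates and a 4-variable cap that is at most 793 fits per
    repetition. Repetitions whose training split misses a class are redrawn.
    """
    candidates = tuple(sorted(config.candidate_variables))
    for v in candidates:
        if v not in cohort.catalog:
            raise ValueError(f"candidate {v!r} not in catalog")
    counts = cohort.group_counts
    if min(counts.values()) == 0:
        raise ValueError("cohort must contain all three groups")
    n_events = counts["case"]
    if config.max_subset_size is None:
        max_k = min(max_subset_size_from_epv(n_events, config.epv), len(candidates))
    else:
        max_k = min(config.max_subset_size, len(candidates))

    M = cohort.symptom_matrix(list(candidates))
    keep = ~np.isnan(M).any(axis=1)
    if not keep.all():
        logger.info("best_subset_select: excluding %d incomplete records",
                    int((~keep).sum()))
    X = M[keep].astype(np.int64)
    y = cohort.group_codes(CLASS_ORDER)[keep]
    nb = len(candidates)
    K = len(CLASS_ORDER)
    full_codes = X @ (1 << np.arange(nb, dtype=np.int64))
    subsets = [S for k in range(1, max_k + 1)
               for S in itertools.combinations(range(nb), k)]

    root = np.random.SeedSequence(config.seed)
    winners: list[tuple[str, ...]] = []
    crit_values: list[float] = []
    redraws = 0
    rep = 0
    while rep < config.repetitions:
        rng = np.random.default_rng(root.spawn(1)[0])
        tr = _stratified_split(rng, y, config.train_fraction)
        if len(np.unique(y[tr])) < K or len(np.unique(y[~tr])) < K:
            redraws += 1
            logger.info("redrawing split: a class is missing")
            continue
        rep += 1
        # aggregate full patterns once per repetition
        parts = {}
        for part, m in (("train", tr), ("test", ~tr)):
            uc, inv = np.unique(full_codes[m], return_inverse=True)
            cnt = np.column_stack([
                np.bincount(inv[y[m] == g], minlength=len(uc))
                for g in range(K)]).astype(float)
            pat = ((uc[:, None] >> np.arange(nb)) & 1).astype(np.int64)
            parts[part] = (pat, cnt)
        best_val, best_S = -np.inf, None
        for S in subsets:
            val = _evaluate_subset(parts, list(S), config)
            if val > best_val + 1e-12:
                best_val, best_S = val, S
        winners.append(tuple(candidates[i] for i in best_S))
        crit_values.append(best_val)
    freq = {v: 0.0 for v in candidates}
    for w in winners:
        for v in w:
            freq[v] += 1.0
    freq = {v: c / len(winners) for v, c in freq.items()}
    final = tuple(sorted(v for v, f in freq.items()
                         if f > config.frequency_threshold))
    return SelectionReport(
        config=config, max_subset_size=max_k, per_rep_winners=winners,
        per_rep_criterion=crit_values, occurrence_frequency=freq,
        final_set=final, redraws=redraws,
    )


def _evaluate_subset(parts, S, config):
    """Fit on the training cells of subset S, score on the test cells.

    Patterns are collapsed to the 2^|S| cells of the subset, so each fit
    works on at most 16 aggregated rows. Returns accuracy or minus the mean
    test deviance (both: larger is better).
    """
    k = len(S)
    ncell = 1 << k
    p2 = 1 << np.arange(k, dtype=np.int64)
    cells = ((np.arange(ncell)[:, None] >> np.arange(k)) & 1).astype(np.int64)
    agg = {}
    for part in ("train", "test"):
        pat, cnt = parts[part]
        cell_of = pat[:, S] @ p2
        C = np.column_stack([
            np.bincount(cell_of, weights=cnt[:, g], minlength=ncell)
            for g in range(cnt.shape[1])])
        agg[part] = C
    Ctr, Cte = agg["train"], agg["test"]
    # reference class = last (non_case); _newton_fit expects it in the last col
    nz = Ctr.sum(axis=1) > 0
    # looser gradient tolerance than a final model fit: criterion values are
    # insensitive at this scale and thousands of fits run per repetition
    beta, _, _, _, _ = _newton_fit(Ctr[nz], cells[nz], ridge=1e-2,
                                   tol=1e-6, max_iter=100)
    eta = np.hstack([np.ones((ncell, 1)), cells.astype(float)]) @ beta.T
    probs = _softmax_probs(eta)
    n_test = Cte.sum()
    if config.criterion == "test_accuracy":
        pred = probs.argmax(axis=1)
        return float(Cte[np.arange(ncell), pred].sum() / n_test)
    ll = float(np.where(Cte > 0,
                        Cte * np.log(np.clip(probs, 1e-300, None)), 0.0).sum())
    return ll / n_test  # minus mean deviance/2; monotone equivalent


def forest_importance(cohort: Cohort, candidates, repetitions: int = 1000,
                      seed: int = 0, train_fraction: float = 0.70,
                      n_estimators: int = 100) -> list[tuple[str, float]]:
    """Random-forest variable importance averaged over repeated subsamples.

    Per repetition a stratified ``train_fraction`` subsample is drawn and an
    ensemble-of-trees classifier fitted; importances are the mean decrease in
    impurity. Returns (symptom_id, mean importance) in descending order.
    """
    candidates = list(candidates)
    M = cohort.symptom_matrix(candidates)
    keep = ~np.isnan(M).any(axis=1)
    X = M[keep]
    y = cohort.group_codes(CLASS_ORDER)[keep]
    root = np.random.SeedSequence(seed)
    total = np.zeros(len(candidates))
    done = 0
    for ss in root.spawn(repetitions):
        rng = np.random.default_rng(ss)
        tr = _stratified_split(rng, y, train_fraction)
        try:
            rf = RandomForestClassifier(
                n_estimators=n_estimators, criterion="gini",
                random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1)
            rf.fit(X[tr], y[tr])
        except Exception:  # pragma: no cover - defensive, fit failures are logged
            logger.warning("forest repetition failed; skipping", exc_info=True)
            continue
        total += rf.feature_importances_
        done += 1
    if done == 0:
        raise RuntimeError("all forest repetitions failed")
    mean_imp = total / done
    order = np.argsort(-mean_imp)
    return [(candidates[i], float(mean_imp[i])) for i in order]
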