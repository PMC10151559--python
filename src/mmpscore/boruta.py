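"""All-relevant feature selection with shadow features (Boruta).

Each iteration appends a row-shuffled "shadow" copy of every undecided
feature, fits a random-forest classifier, and records a *hit* for every
undecided feature whose importance beats the best shadow importance.  After
each iteration a two-sided binomial test on the hit count (success
probability 0.5, Bonferroni-corrected across the undecided features) either
confirms or rejects features; whatever remains undecided after ``max_iter``
iterations is tentative.  With a single iteration no binomial test can reach
significance, so everything stays tentative — the intended degenerate
behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger("mmpscore")


@dataclass
class BorutaResult:
    """Outcome of a Boruta run; the three sets partition the input features."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    n_iterations: int
    history: pd.DataFrame  # per-iteration importance of each feature

    def __post_init__(self) -> None:
        sets = [set(self.confirmed), set(self.rejected), set(self.tentative)]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        assert total == len(union), "confirmed/rejected/tentative must be disjoint"


def boruta_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 300,
) -> BorutaResult:
    """Run Boruta on a samples x features matrix against labels ``y``.

    Parameters
    ----------
    X
        Feature matrix; a DataFrame keeps its column names, an array gets
        ``F000``-style names.
    y
        Classification target (here: consensus cluster labels).
    alpha
        Familywise level of the per-iteration binomial decisions
        (Bonferroni-corrected across currently undecided features).
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"F{i:03d}" for i in range(Xa.shape[1])]
    if not np.isfinite(Xa).all():
        raise ValueError("X contains non-finite values")
    if Xa.shape[0] < 5:
        raise ValueError("Boruta needs >=5 samples")
    y = np.asarray(y)
    n, p = Xa.shape

    rng = np.random.default_rng(seed)
    undecided = list(range(p))
    confirmed: list[int] = []
    rejected: list[int] = []
    hits = np.zeros(p, dtype=int)
    trials = 0
    history_rows = []

    for it in range(1, max_iter + 1):
        idx = np.array(undecided)
        # pad the shadow ensemble to >=5 columns so the max-shadow threshold
        # stays a meaningful null reference when few features remain undecided
        shadow_src = idx
        while shadow_src.size < min(5, p):
            shadow_src = np.concatenate([shadow_src, idx])
        shadows = Xa[:, shadow_src].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([Xa, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:p], imp[p:]
        thresh = shadow_imp.max() if shadow_imp.size else 0.0
        hits[idx] += (real_imp[idx] > thresh).astype(int)
        trials += 1
        history_rows.append(pd.Series(real_imp, index=names, name=it))

        alpha_corr = alpha / p  # Bonferroni across all input features
        still = []
        for f in undecided:
            p_hi = stats.binom.sf(hits[f] - 1, trials, 0.5)   # P(X >= hits)
            p_lo = stats.binom.cdf(hits[f], trials, 0.5)      # P(X <= hits)
            if p_hi < alpha_corr:
                confirmed.append(f)
            elif p_lo < alpha_corr:
                rejected.append(f)
            else:
                still.append(f)
        undecided = still
        if not undecided:
            break

    history = pd.DataFrame(history_rows)
    logger.info("boruta_select: %d confirmed, %d rejected, %d tentative after %d iteration(s)",
                len(confirmed), len(rejected), len(undecided), trials)
    return BorutaResult(
        confirmed=[names[f] for f in sorted(confirmed)],
        rejected=[names[f] for f in sorted(rejected)],
        tentative=[names[f] for f in sorted(undecided)],
        n_iterations=trials,
        history=history,
    )
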