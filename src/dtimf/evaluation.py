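"""Cross-validation protocol for cold-start interaction prediction.

Two scenarios are supported, both of which partition *entities* rather than
pairs because the masking semantics act on whole rows or columns:

* ``CV_d`` — drugs are split into folds; for a test fold every row of Z
  belonging to it is zeroed in the training matrix, simulating drugs with no
  known targets.
* ``CV_t`` — the same with targets and columns, simulating targets with no
  known drugs.

Each of ``n_repeats`` repetitions draws a fresh fold partition; metrics
(AUC, AUPR) are computed per fold over all pairs involving the held-out
entities, with the zero entries treated as negatives — the standard, if
label-noisy, convention for these benchmarks. Aggregates are reported both
across all repeat x fold cells and across repeat means, since published
tables rarely say which of the two their standard deviations use.

Hyperparameter selection, when a grid is given, runs on an inner hold-out of
the *training* entities of each fold (same masking scenario), so the test
fold never influences the choice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DomainError, NumericalError, UndefinedMetricError
from .graph import build_graph_operators
from .io import InteractionData, SimilarityMatrix
from .solver import SolverConfig, solve

logger = logging.getLogger(__name__)

__all__ = ["CVScheme", "CVResult", "DEFAULT_GRID", "make_folds",
           "mask_for_fold", "auc_score", "aupr_score", "grid_search",
           "run_cv"]

SCENARIOS = ("CV_d", "CV_t")

#: Default hyperparameter grid: rank from {50, 100}, graph weights from
#: {0, 1e-4, 1e-3, 1e-2, 1e-1}.
DEFAULT_GRID = {
    "k": [50, 100],
    "lambda_d": [0.0, 1e-4, 1e-3, 1e-2, 1e-1],
    "lambda_t": [0.0, 1e-4, 1e-3, 1e-2, 1e-1],
}


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scenario and fold structure."""

    scenario: str = "CV_t"
    n_folds: int = 10
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise DomainError(f"scenario must be one of {SCENARIOS}")
        if self.n_folds < 2:
            raise DomainError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise DomainError("n_repeats must be at least 1")


@dataclass
class CVResult:
    """Per-fold metric table and its aggregates.

    ``per_fold`` has one row per (repeat, fold) cell with columns
    ``auc``, ``aupr``, ``n_test``, ``n_pos`` and, when grid search was
    active, the chosen ``k``, ``lambda_d``, ``lambda_t``. Degenerate folds
    (no positives among test pairs) are absent from the table.
    """

    per_fold: pd.DataFrame
    mean_auc: float
    sd_auc: float
    mean_aupr: float
    sd_aupr: float
    sd_auc_repeat_means: float
    sd_aupr_repeat_means: float
    chosen_hyperparams: list = field(default_factory=list)
    n_skipped: int = 0

    @staticmethod
    def from_table(per_fold: pd.DataFrame, chosen=None,
                   n_skipped: int = 0) -> "CVResult":
        def _sd(x):
            return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

        rep_auc = per_fold.groupby("repeat")["auc"].mean()
        rep_aupr = per_fold.groupby("repeat")["aupr"].mean()
        return CVResult(
            per_fold=per_fold,
            mean_auc=float(per_fold["auc"].mean()),
            sd_auc=_sd(per_fold["auc"]),
            mean_aupr=float(per_fold["aupr"].mean()),
            sd_aupr=_sd(per_fold["aupr"]),
            sd_auc_repeat_means=_sd(rep_auc),
            sd_aupr_repeat_means=_sd(rep_aupr),
            chosen_hyperparams=chosen or [],
            n_skipped=n_skipped,
        )


def make_folds(ids, scheme: CVScheme, repeat: int = 0) -> list[np.ndarray]:
    """Seeded partition of entity indices into near-equal disjoint folds.

    ``ids`` is the identifier list of the partitioned axis; folds are
    returned as arrays of integer positions. The partition is a pure
    function of ``(scheme.seed, repeat)``.
    """
    n = len(ids)
    if n < scheme.n_folds:
        raise DomainError(f"cannot split {n} entities into "
                          f"{scheme.n_folds} folds")
    rng = np.random.default_rng((scheme.seed, repeat))
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, scheme.n_folds)]


def mask_for_fold(Z: np.ndarray, fold, scenario: str):
    """Zero the rows (CV_d) or columns (CV_t) of the fold entities.

    Returns ``(Z_train, test_pairs)`` where ``test_pairs`` is an (L, 2)
    integer array of all pairs involving a fold entity. The training Omega
    is recomputed downstream from ``Z_train``.
    """
    if scenario not in SCENARIOS:
        raise DomainError(f"scenario must be one of {SCENARIOS}")
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    fold = np.asarray(fold, dtype=int)
    Z_train = Z.copy()
    if scenario == "CV_d":
        Z_train[fold, :] = 0.0
        test_pairs = np.array([(i, j) for i in fold for j in range(m)],
                              dtype=int).reshape(-1, 2)
    else:
        Z_train[:, fold] = 0.0
        test_pairs = np.array([(i, j) for j in fold for i in range(n)],
                              dtype=int).reshape(-1, 2)
    return Z_train, test_pairs


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "metric undefined: need at least one positive and one negative")


def auc_score(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Equivalent to the Mann-Whitney U statistic normalized by the number of
    positive-negative pairs, and to the area under the ROC curve.
    """
    labels = np.asarray(labels, dtype=float)
    _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr_score(labels, scores) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Uses the non-interpolated step method (precision at each recall
    increment), the convention these benchmarks report.
    """
    labels = np.asarray(labels, dtype=float)
    _check_labels(labels)
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


def _fit_and_score(Z_full, Z_train, test_pairs, graph_d, graph_t,
                   config: SolverConfig):
    """Fit the solver on Z_train and score the test pairs against Z_full."""
    omega = Z_train == 1.0
    state, _ = solve(Z_train, omega, graph_d.L_norm, graph_t.L_norm, config)
    scores = state.M[test_pairs[:, 0], test_pairs[:, 1]]
    labels = Z_full[test_pairs[:, 0], test_pairs[:, 1]]
    return labels, scores


def _grid_points(grid: dict):
    keys = ("lambda_d", "lambda_t", "k")
    values = [sorted(grid.get(key, [None])) for key in keys]
    points = []
    for lam_d, lam_t, k in itertools.product(*values):
        point = {}
        if lam_d is not None:
            point["lambda_d"] = lam_d
        if lam_t is not None:
            point["lambda_t"] = lam_t
        if k is not None:
            point["k"] = k
        points.append(point)
    return points


def grid_search(train_data, scheme: CVScheme, grid: dict,
                config: SolverConfig | None = None) -> dict:
    """Select hyperparameters on an inner hold-out of the training entities.

    ``train_data`` is the ``(InteractionData, drug_sim, target_sim)`` triple
    with the outer test fold already masked. One inner fold of entities
    (same scenario, roughly 1/n_folds of them) is masked in turn; each grid
    point is fitted on the remainder and scored by AUPR on the inner pairs.
    The point maximizing inner AUPR wins; ties go to smaller lambda_d, then
    smaller lambda_t, then smaller k (the enumeration order).

    Returns the chosen point as a dict of the grid's keys.
    """
    if not grid or not any(grid.values()):
        raise DomainError("hyperparameter grid is empty")
    points = _grid_points(grid)
    if len(points) == 1:
        return points[0]
    interactions, drug_sim, target_sim = train_data
    config = config or SolverConfig()
    graph_d = build_graph_operators(drug_sim.S, config.p)
    graph_t = build_graph_operators(target_sim.S, config.p)

    axis_ids = (interactions.drug_ids if scheme.scenario == "CV_d"
                else interactions.target_ids)
    inner_scheme = replace(scheme, seed=scheme.seed + 1)
    inner_fold = make_folds(axis_ids, inner_scheme, repeat=0)[0]
    Z_inner, inner_pairs = mask_for_fold(interactions.Z, inner_fold,
                                         scheme.scenario)

    best_point, best_aupr = None, -np.inf
    for point in points:
        cand = replace(config, **point)
        try:
            labels, scores = _fit_and_score(interactions.Z, Z_inner,
                                            inner_pairs, graph_d, graph_t,
                                            cand)
            val = aupr_score(labels, scores)
        except UndefinedMetricError:
            logger.warning("inner fold degenerate; skipping grid point %s",
                           point)
            continue
        except NumericalError as exc:
            # large lambda/penalty ratios can diverge; such points simply
            # lose the selection
            logger.warning("grid point %s diverged (%s); skipping", point, exc)
            continue
        if val > best_aupr:
            best_point, best_aupr = point, val
    if best_point is None:
        logger.warning("grid search found no scorable point; keeping defaults")
        return {}
    return best_point


def run_cv(dataset, scheme: CVScheme, config: SolverConfig,
           grid: dict | None = None) -> CVResult:
    """Run repeated k-fold cold-start cross-validation.

    ``dataset`` is the ``(InteractionData, drug_sim, target_sim)`` triple.
    For every repeat and fold the fold entities are masked, hyperparameters
    optionally selected on an inner split, the solver fitted on the masked
    matrix, and all pairs of the fold entities scored from the prediction
    matrix M. Folds whose test pairs contain no positive are skipped with a
    logged warning. Solver failures are recorded and do not abort the run.
    """
    interactions, drug_sim, target_sim = dataset
    if drug_sim.dim != interactions.n_drugs:
        raise DomainError("drug similarity dimension does not match Z rows")
    if target_sim.dim != interactions.n_targets:
        raise DomainError("target similarity dimension does not match Z columns")
    graph_d = build_graph_operators(drug_sim.S, config.p)
    graph_t = build_graph_operators(target_sim.S, config.p)
    axis_ids = (interactions.drug_ids if scheme.scenario == "CV_d"
                else interactions.target_ids)

    rows, chosen_log, n_skipped = [], [], 0
    for repeat in range(scheme.n_repeats):
        folds = make_folds(axis_ids, scheme, repeat=repeat)
        for fold_idx, fold in enumerate(folds):
            Z_train, test_pairs = mask_for_fold(interactions.Z, fold,
                                                scheme.scenario)
            fold_config = config
            chosen = {}
            if grid:
                train_interactions = InteractionData(
                    interactions.drug_ids, interactions.target_ids, Z_train)
                chosen = grid_search(
                    (train_interactions, drug_sim, target_sim),
                    scheme, grid, config)
                fold_config = replace(config, **chosen)
            try:
                labels, scores = _fit_and_score(
                    interactions.Z, Z_train, test_pairs, graph_d, graph_t,
                    fold_config)
                auc = auc_score(labels, scores)
                aupr = aupr_score(labels, scores)
            except UndefinedMetricError:
                logger.warning("repeat %d fold %d: no positives among test "
                               "pairs; skipped", repeat, fold_idx)
                n_skipped += 1
                continue
            except Exception as exc:  # solver failure: record, keep going
                logger.warning("repeat %d fold %d failed: %s",
                               repeat, fold_idx, exc)
                n_skipped += 1
                continue
            row = {"repeat": repeat, "fold": fold_idx, "auc": auc,
                   "aupr": aupr, "n_test": len(test_pairs),
                   "n_pos": int(labels.sum())}
            row.update(chosen)
            rows.append(row)
            if chosen:
                chosen_log.append({"repeat": repeat, "fold": fold_idx,
                                   **chosen})
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise UndefinedMetricError("every fold was degenerate or failed")
    return CVResult.from_table(per_fold, chosen=chosen_log,
                               n_skipped=n_skipped)
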