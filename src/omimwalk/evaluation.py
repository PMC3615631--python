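"""Leave-one-out cross-validation, ROC construction and the restart sweep.

For each verified (miRNA, disease) pair, the disease is withheld, the
miRNA's remaining diseases become the restart seeds, and the steady-state
probabilities rank the withheld disease among all diseases not currently
associated with the miRNA. Ranks use the midrank convention for ties and
are pooled across trials as rank percentiles (rank - 0.5) / n_candidates,
since candidate-set sizes differ between miRNAs.

The primary AUC is the Mann-Whitney rank statistic: the probability that a
withheld true disease outranks a random negative candidate, computed per
trial as (n_candidates - rank) / (n_candidates - 1) and averaged. A
trapezoidal integral of the pooled ROC curve is kept as a cross-check and
for plotting.

miRNAs whose single known disease is withheld have an empty seed set; the
default policy restarts uniformly over the whole disease universe
(``uniform``), with ``skip`` available to drop such trials instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import AssociationSet, SimilarityMatrix
from .rwr import RWRConfig, TransitionMatrix, normalize, rwr_steady_state

logger = logging.getLogger(__name__)

EMPTY_SEED_POLICIES = ("skip", "uniform")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one leave-one-out trial.

    ``rank`` is the midrank of the withheld disease among the candidates
    (may be half-integral under ties); ``n_candidates`` counts the withheld
    disease itself.
    """

    mirna_id: str
    left_out_disease: str
    rank: float
    n_candidates: int

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.n_candidates):
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates}]"
            )

    @property
    def rank_percentile(self) -> float:
        """(rank - 0.5) / n_candidates, pooling unequal candidate sets."""
        return (self.rank - 0.5) / self.n_candidates

    @property
    def trial_auc(self) -> float:
        """Probability the withheld disease outranks a random negative."""
        if self.n_candidates == 1:
            return 1.0
        return (self.n_candidates - self.rank) / (self.n_candidates - 1)


@dataclass(frozen=True)
class RocCurve:
    """Pooled ROC curve with its AUC.

    ``points`` are (threshold, sensitivity, specificity) triples over a
    percentile grid; ``auc`` is the rank-identity value, ``auc_trapezoid``
    the trapezoidal integral of the curve.
    """

    points: tuple[tuple[float, float, float], ...]
    auc: float
    auc_trapezoid: float


def _drop_unmapped(assoc: AssociationSet, universe: tuple[str, ...]) -> AssociationSet:
    known = set(universe)
    kept = {(m, d) for m, d in assoc.pairs if d in known}
    dropped = assoc.n_pairs - len(kept)
    if dropped:
        logger.warning(
            "dropped %d association(s) whose disease is absent from the "
            "similarity matrix",
            dropped,
        )
    return AssociationSet(frozenset(kept))


def loocv(
    assoc: AssociationSet,
    W: TransitionMatrix,
    config: RWRConfig | None = None,
    empty_seed_policy: str = "uniform",
) -> list[TrialResult]:
    """Leave-one-out cross-validation over all retained associations.

    Associations whose disease is missing from the walk universe are
    dropped with a logged count. Trials of one miRNA share a single batched
    walk (one seed column per withheld disease).
    """
    if empty_seed_policy not in EMPTY_SEED_POLICIES:
        raise ValueError(f"unknown empty-seed policy {empty_seed_policy!r}")
    config = config or RWRConfig()
    if not assoc.pairs:
        raise ValueError("empty association set")
    assoc = _drop_unmapped(assoc, W.disease_ids)
    if not assoc.pairs:
        raise ValueError("no association maps into the similarity universe")

    index = {d: i for i, d in enumerate(W.disease_ids)}
    n = W.n
    results: list[TrialResult] = []
    for mirna in assoc.mirna_ids:
        diseases = sorted(assoc.diseases_of(mirna))
        trials: list[str] = []
        columns: list[np.ndarray] = []
        for left_out in diseases:
            seeds = [d for d in diseases if d != left_out]
            if not seeds:
                if empty_seed_policy == "skip":
                    continue
                p0 = np.full(n, 1.0 / n)
            else:
                p0 = np.zeros(n)
                p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
            trials.append(left_out)
            columns.append(p0)
        if not trials:
            continue
        P = rwr_steady_state(W, np.column_stack(columns), config)
        for k, left_out in enumerate(trials):
            seeds_idx = [index[d] for d in diseases if d != left_out]
            mask = np.ones(n, dtype=bool)
            mask[seeds_idx] = False  # candidates = non-associated + left-out
            scores = P[mask, k]
            ranks = rankdata(-scores, method="average")
            pos = int(np.flatnonzero(np.flatnonzero(mask) == index[left_out])[0])
            results.append(
                TrialResult(
                    mirna_id=mirna,
                    left_out_disease=left_out,
                    rank=float(ranks[pos]),
                    n_candidates=int(mask.sum()),
                )
            )
    return results


def roc_from_trials(
    trials: list[TrialResult], n_thresholds: int = 1000
) -> RocCurve:
    """Build the pooled ROC curve and AUC from leave-one-out trials.

    Sensitivity at threshold t is the fraction of withheld diseases whose
    rank percentile is <= t; specificity is the fraction of pooled negative
    candidates ranked worse than t. The reported AUC is the rank-identity
    (Mann-Whitney) value, invariant to the threshold grid.
    """
    if not trials:
        raise ValueError("no trials")
    pos = np.array([t.rank_percentile for t in trials])
    negs = _pooled_negatives(trials)
    grid = np.linspace(0.0, 1.0, n_thresholds + 1)
    sens = np.searchsorted(np.sort(pos), grid, side="right") / pos.size
    fpr = np.searchsorted(np.sort(negs), grid, side="right") / negs.size
    spec = 1.0 - fpr
    auc_rank = float(np.mean([t.trial_auc for t in trials]))
    auc_trap = float(np.trapezoid(sens, fpr))
    points = tuple(zip(grid.tolist(), sens.tolist(), spec.tolist()))
    return RocCurve(points=points, auc=auc_rank, auc_trapezoid=auc_trap)


def _pooled_negatives(trials: list[TrialResult]) -> np.ndarray:
    """Midrank percentiles of all non-withheld candidates, pooled.

    In a trial with midrank rho among n candidates, the negatives occupy
    the remaining rank mass; their percentiles are reconstructed from the
    rank positions 1..n with the withheld disease's mass removed.
    """
    parts = []
    for t in trials:
        n = t.n_candidates
        all_pct = (np.arange(1, n + 1) - 0.5) / n
        # remove the position closest to the positive's midrank
        drop = int(np.clip(round(t.rank) - 1, 0, n - 1))
        parts.append(np.delete(all_pct, drop))
    return np.concatenate(parts) if parts else np.empty(0)


def parameter_sweep(
    assoc: AssociationSet,
    sim: SimilarityMatrix,
    r_values,
    config: RWRConfig | None = None,
    empty_seed_policy: str = "uniform",
) -> list[tuple[float, float]]:
    """Run LOOCV at each restart probability and report (r, AUC) rows.

    Rows follow the input order of ``r_values``; the argmax r is logged.
    """
    base = config or RWRConfig()
    rows: list[tuple[float, float]] = []
    for r in r_values:
        cfg = RWRConfig(
            restart_probability=float(r),
            convergence_tolerance=base.convergence_tolerance,
            max_iterations=base.max_iterations,
            normalization=base.normalization,
        )
        W = normalize(sim, scheme=cfg.normalization)
        trials = loocv(assoc, W, cfg, empty_seed_policy=empty_seed_policy)
        curve = roc_from_trials(trials)
        rows.append((float(r), curve.auc))
    best_r, best_auc = max(rows, key=lambda row: row[1])
    logger.info("best restart probability r=%.3g (AUC=%.4f)", best_r, best_auc)
    return rows
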