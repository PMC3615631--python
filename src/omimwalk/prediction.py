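"""Comprehensive prediction of novel disease candidates per miRNA.

Trained on all verified associations: for a miRNA of interest, every
disease already confirmed for it becomes a restart seed, every other
disease in the similarity universe a candidate, and candidates are ranked
by steady-state visiting probability. Ties are broken by disease id
ascending so that output is byte-identical across runs.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import AssociationSet, PredictionRecord, SimilarityMatrix
from .rwr import RWRConfig, TransitionMatrix, initial_vector, normalize, rwr_steady_state

logger = logging.getLogger(__name__)


def score_candidates(
    mirna_id: str,
    assoc: AssociationSet,
    W: TransitionMatrix,
    config: RWRConfig | None = None,
) -> list[PredictionRecord]:
    """Rank all non-associated diseases for one miRNA.

    Seeds are the miRNA's known diseases that map into the walk universe;
    raises if the miRNA is unknown or none of its diseases map.
    """
    config = config or RWRConfig()
    if mirna_id not in assoc.mirna_ids:
        raise KeyError(f"unknown miRNA {mirna_id!r}")
    universe = set(W.disease_ids)
    known = assoc.diseases_of(mirna_id)
    seeds = sorted(known & universe)
    if not seeds:
        raise ValueError(
            f"miRNA {mirna_id!r} has no seed disease in the similarity universe"
        )
    p0 = initial_vector(seeds, W.disease_ids)
    p_inf = rwr_steady_state(W, p0, config)
    candidates = [
        (d, float(p_inf[i]))
        for i, d in enumerate(W.disease_ids)
        if d not in known
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return [
        PredictionRecord(mirna_id=mirna_id, disease_id=d, score=s, rank=k)
        for k, (d, s) in enumerate(candidates, start=1)
    ]


def predict_all(
    assoc: AssociationSet,
    sim: SimilarityMatrix,
    config: RWRConfig | None = None,
    top_k: int = 20,
) -> list[PredictionRecord]:
    """Top-k candidate diseases for every miRNA with a mappable seed.

    k truncates but never pads; miRNAs with no mappable seed disease are
    skipped with a warning. Output is deterministic.
    """
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    config = config or RWRConfig()
    W = normalize(sim, scheme=config.normalization)
    universe = set(W.disease_ids)
    records: list[PredictionRecord] = []
    skipped = 0
    for mirna in assoc.mirna_ids:
        if not (assoc.diseases_of(mirna) & universe):
            skipped += 1
            continue
        records.extend(score_candidates(mirna, assoc, W, config)[:top_k])
    if skipped:
        logger.warning(
            "skipped %d miRNA(s) with no seed disease in the similarity matrix",
            skipped,
        )
    return records
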