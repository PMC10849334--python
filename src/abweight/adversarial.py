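"""Adversarial (train-vs-test) marker weighting for a held-out family.

To quantify how strongly each marker separates a held-out family from the
remaining families, a fictitious binary response labels every line of the
held-out family 1 and every other line 0.  The shadow-feature relevance
run on (M, labels) yields per-marker importance scores; their inverses,
normalized to sum p, are the AB weights — markers that discriminate the
family get attenuated in the weighted GRM.  Weights are a pure function
of genotypes and family labels; no phenotype value enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boruta import BorutaConfig, boruta_run
from .data import Dataset
from .grm import WeightVector, weights_from_importance


@dataclass
class AdversarialLabels:
    """Fictitious response: 1 for the held-out family, 0 elsewhere."""

    y_f: np.ndarray
    held_out_family: str


def adversarial_labels(dataset: Dataset, family: str) -> AdversarialLabels:
    """Binary labels over all genotyped lines for one held-out family."""
    family = str(family)
    families = dataset.families
    if family not in families:
        raise ValueError(f"family {family!r} not present in dataset")
    if len(families) < 2:
        raise ValueError(
            "need at least 2 families to form an adversarial train/test split"
        )
    labels = dataset.family_labels()
    y_f = (labels == family).astype(int)
    if y_f.sum() == 0 or y_f.sum() == y_f.size:
        raise ValueError("both classes must be non-empty")
    return AdversarialLabels(y_f=y_f, held_out_family=family)


def ab_weights(
    dataset: Dataset,
    family: str,
    config: BorutaConfig | None = None,
    floor_fraction: float = 1e-3,
) -> WeightVector:
    """AB marker weights for one held-out family.

    Runs the shadow-feature relevance engine on the standardized marker
    matrix of ALL lines (training and held-out) against the fictitious
    family labels, then inverts and normalizes the importance scores.
    The run is re-seeded deterministically as ``seed + family index`` so
    each family gets an independent but reproducible stream.
    """
    config = config or BorutaConfig()
    labels = adversarial_labels(dataset, family)
    fam_index = dataset.families.index(str(family))
    fold_config = BorutaConfig(
        n_iterations=config.n_iterations,
        trees_per_forest=config.trees_per_forest,
        alpha=config.alpha,
        seed=(config.seed + fam_index) % (2**31 - 1),
        max_depth=config.max_depth,
    )
    result = boruta_run(dataset.markers.M, labels.y_f, fold_config)
    return weights_from_importance(result.IS, floor_fraction=floor_fraction)
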