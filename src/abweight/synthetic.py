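"""Family-structured genotype/phenotype simulator with marker mismatch.

Marker allele frequencies are drawn once from Beta(2, 2); each family's
lines are independent Hardy-Weinberg draws from the family's frequency
vector (free recombination, no linkage).  One designated family — always
the first — has the frequencies of a chosen set of "mismatch" markers
shifted by +delta (clipped to [0.05, 0.95]), creating exactly the
train/test marker-distribution mismatch the adversarial weighting is
meant to detect; with delta = 0 every family is an exchangeable sample
from the same genotype distribution, so a two-sample allele-frequency
test flags only the nominal false-positive fraction of markers.
Quantitative trait loci are drawn from the non-mismatch markers (the
mismatch set models group-private, non-causal structure), their additive
values are rescaled so the realized genic variance fraction equals the
target heritability, and environment main effects, line-by-environment
deviations and Gaussian noise complete the phenotype.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, MarkerMatrix, PhenotypeTable, write_dataset


@dataclass
class SimConfig:
    """Simulation settings; defaults give the single-environment
    five-family mismatch scenario used throughout the test battery."""

    n_families: int = 5
    lines_per_family: int = 30
    p: int = 500
    n_qtl: int = 450
    n_environments: int = 1
    h2: float = 0.5
    gxe_fraction: float = 0.0
    mismatch_markers: int = 50
    mismatch_delta: float = 0.4
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if not 0 <= self.mismatch_delta <= 1:
            raise ValueError("mismatch_delta must be in [0, 1]")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        if self.mismatch_markers > self.p:
            raise ValueError("mismatch_markers cannot exceed p")
        if self.n_qtl > self.p - self.mismatch_markers:
            raise ValueError(
                "n_qtl cannot exceed the number of non-mismatch markers"
            )
        if self.h2 + self.gxe_fraction >= 1:
            raise ValueError("h2 + gxe_fraction must be < 1")
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        if self.n_environments < 1:
            raise ValueError("need at least 1 environment")


def simulate_families(config: SimConfig) -> tuple[Dataset, dict]:
    """Simulate a multi-family dataset plus a metadata sidecar.

    Returns the validated Dataset and a metadata dict recording the
    mismatch-marker IDs, QTL IDs and effects, and the true variance
    components — everything a test needs to check that the adversarial
    weighting attenuates exactly the planted structure.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p
    marker_ids = [f"M{k:04d}" for k in range(p)]
    base_freq = rng.beta(2.0, 2.0, size=p)
    mismatch_idx = rng.choice(p, size=config.mismatch_markers, replace=False)
    mismatch_idx.sort()

    dosages = []
    line_ids = []
    family_ids = []
    for f in range(config.n_families):
        freq = base_freq.copy()
        if f == 0 and config.mismatch_markers:
            freq[mismatch_idx] = np.clip(
                freq[mismatch_idx] + config.mismatch_delta, 0.05, 0.95
            )
        dosages.append(
            rng.binomial(2, freq, size=(config.lines_per_family, p)).astype(float)
        )
        line_ids += [f"F{f + 1}_L{j + 1:02d}" for j in range(config.lines_per_family)]
        family_ids += [f"F{f + 1}"] * config.lines_per_family
    X = np.vstack(dosages)

    markers = MarkerMatrix.from_dosage(X, line_ids, marker_ids)
    kept = {m: i for i, m in enumerate(markers.marker_ids)}
    mismatch_ids = [marker_ids[k] for k in mismatch_idx if marker_ids[k] in kept]

    # QTL among the surviving non-mismatch markers
    candidates = [m for m in markers.marker_ids if m not in set(mismatch_ids)]
    qtl_ids = list(
        rng.choice(candidates, size=min(config.n_qtl, len(candidates)), replace=False)
    )
    qtl_cols = [kept[m] for m in qtl_ids]
    effects = rng.standard_normal(len(qtl_cols))
    g_raw = (markers.X[:, qtl_cols] - markers.X[:, qtl_cols].mean(axis=0)) @ effects
    sd = g_raw.std()
    scale = np.sqrt(config.h2) / sd if sd > 0 else 0.0
    g = g_raw * scale

    sigma2_gxe = config.gxe_fraction if config.n_environments > 1 else 0.0
    sigma2_e = 1.0 - config.h2 - sigma2_gxe
    env_ids = [f"E{i + 1}" for i in range(config.n_environments)]
    env_effects = (
        rng.standard_normal(config.n_environments)
        if config.n_environments > 1
        else np.zeros(1)
    )

    n = len(line_ids)
    records = []
    for i, env in enumerate(env_ids):
        ge = (
            rng.standard_normal(n) * np.sqrt(sigma2_gxe)
            if sigma2_gxe > 0
            else np.zeros(n)
        )
        noise = rng.standard_normal(n) * np.sqrt(sigma2_e)
        y = config.mu + env_effects[i] + g + ge + noise
        for j in range(n):
            records.append(
                {
                    "line": line_ids[j],
                    "family": family_ids[j],
                    "env": env,
                    "trait": "trait1",
                    "value": y[j],
                }
            )
    phenotypes = PhenotypeTable(pd.DataFrame(records))
    dataset = Dataset(markers, phenotypes)
    meta = {
        "config": asdict(config),
        "mismatch_markers": mismatch_ids,
        "qtl": dict(zip(qtl_ids, effects.tolist())),
        "genetic_value_scale": float(scale),
        "variance_components": {
            "sigma2_g": config.h2,
            "sigma2_gE": sigma2_gxe,
            "sigma2_e": sigma2_e,
        },
        "true_genetic_values": dict(zip(line_ids, g.tolist())),
    }
    return dataset, meta


def write_simulation(dataset: Dataset, meta: dict, outdir: str | Path) -> dict:
    """Write genotype.csv, phenotype.csv and meta.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotype.csv",
        "phenotypes": outdir / "phenotype.csv",
        "meta": outdir / "meta.json",
    }
    write_dataset(dataset, paths["genotypes"], paths["phenotypes"])
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
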