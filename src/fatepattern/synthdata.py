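"""Synthetic ICM-organoid tables emulating the experimental data schema.

Generates organoid cell tables (organoid_id, stage, batch, CentroidX/Y/Z,
NANOG, GATA6 and a ground-truth ``class`` column) with the statistical
structure of inner-cell-mass organoids: two stages with mean cell counts
441.73 (24 h) and 1041.24 (48 h), four NANOG/GATA6 expression classes, and
a radial enrichment of GATA6-high (N-G+) cells at the organoid rim whose
strength is a single knob.  Positions are near-uniform in a ball with a
minimum-separation constraint; expression levels are lognormal with
class-dependent means separated well beyond their spread, so 2-means
clustering of the committed classes is essentially noiseless.

These tables are synthetic stand-ins for real segmented microscopy data:
they reproduce schema and summary structure, not imaging noise, batch
effects or biological covariation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fatepattern.fates import FATE_CODES

__all__ = ["ICMProfile", "synth_icm_organoid", "synth_dataset_E"]

_DEFAULT_MIXTURES = {
    "24 h": {"N+G+": 0.40, "N-G+": 0.22, "N-G-": 0.08, "N+G-": 0.30},
    "48 h": {"N+G+": 0.15, "N-G+": 0.45, "N-G-": 0.05, "N+G-": 0.35},
}
_DEFAULT_RIM = {"24 h": 1.0, "48 h": 4.0}
# lognormal expression model: log-means per (class, channel); sd 0.3
_LOG_HIGH, _LOG_LOW, _LOG_SD = np.log(200.0), np.log(20.0), 0.3
_NANOG_HIGH = {"N+G+", "N+G-"}
_GATA6_HIGH = {"N+G+", "N-G+"}


@dataclass(frozen=True)
class ICMProfile:
    """Generation profile of one synthetic ICM organoid stage."""

    stage: str = "48 h"
    mean_cells: float | None = None  # default 441.73 (24 h) / 1041.24 (48 h)
    rim_strength: float | None = None  # logistic slope of P(N-G+) vs radius
    mixture: dict = field(default_factory=dict)  # fate-class proportions
    min_separation: float = 1.0  # in units of the mean cell spacing
    batch_shift: float = 0.0  # multiplicative per-batch expression shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("24 h", "48 h"):
            raise ValueError("stage must be '24 h' or '48 h'")
        mix = self.resolved_mixture()
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("fate mixture must sum to 1")
        if self.resolved_mean_cells() <= 0:
            raise ValueError("mean cell count must be positive")

    def resolved_mean_cells(self) -> float:
        if self.mean_cells is not None:
            return self.mean_cells
        return 441.73 if self.stage == "24 h" else 1041.24

    def resolved_rim(self) -> float:
        if self.rim_strength is not None:
            return self.rim_strength
        return _DEFAULT_RIM[self.stage]

    def resolved_mixture(self) -> dict:
        return self.mixture or _DEFAULT_MIXTURES[self.stage]


def _ball_positions(n: int, rng: np.random.Generator, min_sep: float) -> np.ndarray:
    """Near-uniform points in a ball with minimum-separation thinning."""
    # radius chosen so n cells at unit spacing fill the ball
    R = (n / 0.5) ** (1.0 / 3.0)  # ~50% packing efficiency at unit separation
    pts = np.empty((n, 3))
    count = 0
    attempts = 0
    max_attempts = 400 * n
    while count < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} cells with separation {min_sep} "
                f"(placed {count}); relax min_separation"
            )
        cand = rng.normal(size=3)
        cand *= R * rng.random() ** (1 / 3) / np.linalg.norm(cand)
        attempts += 1
        if count and np.min(np.linalg.norm(pts[:count] - cand, axis=1)) < min_sep:
            continue
        pts[count] = cand
        count += 1
    return pts


def synth_icm_organoid(profile: ICMProfile, organoid_id: int = 0,
                       batch: int = 0) -> pd.DataFrame:
    """Generate one synthetic ICM organoid as an experimental-style table.

    Cell count ~ Poisson around the stage mean; P(N-G+) grows logistically
    with normalized radius at slope ``rim_strength``; the uncommitted
    classes (N+G+, N-G-) are placed uniformly; NANOG/GATA6 are lognormal
    with class-consistent high/low means.
    """
    rng = np.random.default_rng(profile.seed)
    n = max(int(rng.poisson(profile.resolved_mean_cells())), 20)
    pos = _ball_positions(n, rng, profile.min_separation)
    radius = np.linalg.norm(pos, axis=1)
    rhat = radius / radius.max()

    mix = profile.resolved_mixture()
    rim = profile.resolved_rim()
    # per-cell class weights: the committed PrE-like class N-G+ is tilted
    # toward the rim, its Epi-like counterpart N+G- toward the centre;
    # uncommitted classes are position-independent
    tilt = 1.0 / (1.0 + np.exp(-rim * (rhat - 0.6)))
    w = np.empty((n, 4))
    w[:, FATE_CODES["N+G+"]] = mix["N+G+"]
    w[:, FATE_CODES["N-G-"]] = mix["N-G-"]
    w[:, FATE_CODES["N-G+"]] = mix["N-G+"] * 2.0 * tilt
    w[:, FATE_CODES["N+G-"]] = mix["N+G-"] * 2.0 * (1.0 - tilt)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(w, axis=1)
    classes = (u[:, None] < cum).argmax(axis=1)

    names = np.array(sorted(FATE_CODES, key=FATE_CODES.get))
    cls_names = names[classes]
    log_nanog = np.where(np.isin(cls_names, list(_NANOG_HIGH)), _LOG_HIGH, _LOG_LOW)
    log_gata6 = np.where(np.isin(cls_names, list(_GATA6_HIGH)), _LOG_HIGH, _LOG_LOW)
    shift = profile.batch_shift * batch
    nanog = np.exp(rng.normal(log_nanog + shift, _LOG_SD))
    gata6 = np.exp(rng.normal(log_gata6 + shift, _LOG_SD))

    return pd.DataFrame({
        "organoid_id": organoid_id,
        "stage": profile.stage,
        "batch": batch,
        "CentroidX": pos[:, 0],
        "CentroidY": pos[:, 1],
        "CentroidZ": pos[:, 2],
        "NANOG": nanog,
        "GATA6": gata6,
        "class": classes,
    })


def synth_dataset_E(seed: int = 0) -> list[pd.DataFrame]:
    """Synthetic analogue of the experimental data set: 34 organoids with
    the 24 h profile and 42 with the 48 h profile (76 total), batch labels
    assigned round-robin over 3 batches."""
    seeds = np.random.SeedSequence(seed).generate_state(76)
    tables = []
    for i in range(76):
        stage = "24 h" if i < 34 else "48 h"
        profile = ICMProfile(stage=stage, seed=int(seeds[i]))
        tables.append(synth_icm_organoid(profile, organoid_id=i, batch=i % 3))
    return tables
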