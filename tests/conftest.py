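"""Shared fixtures: canonical parameter sets and series builders."""

import numpy as np
import pytest

from clonalgrowth import (
    BiDoseRespParams,
    BiHillParams,
    LogisticParams,
    ModelFamily,
    TraitSeries,
    evaluate,
)

# population-level parameter sets with a plant-height-like logistic, a
# leaf-area-like rise-and-decline, and a rhizome-like bimodal trajectory
LOGISTIC_POP = LogisticParams(A1=0.0, A2=100.0, x0=110.0, p=8.0)
BIHILL_POP = BiHillParams(Pm=249.0, Ka=120.0, Ha=6.0, Ki=260.0, Hi=8.0)
BDR_POP = BiDoseRespParams(A1=0.0, A2=200.0, L1=162.0, L2=256.0, h1=0.05, h2=0.08, P=0.6)

ABOVEGROUND_DOYS = np.arange(84.0, 310.0, 5.0)  # 46 surveys, late Mar - early Nov
RHIZOME_DOYS = np.arange(56.0, 347.0, 10.0)  # 30 surveys, late Feb - mid Dec

FAMILY_CASES = [
    (ModelFamily.LOGISTIC, LOGISTIC_POP, ABOVEGROUND_DOYS, "plant_height"),
    (ModelFamily.BIHILL, BIHILL_POP, ABOVEGROUND_DOYS, "leaf_area"),
    (ModelFamily.BIDOSERESP, BDR_POP, RHIZOME_DOYS, "rhizome_length"),
]


def sample_series(
    family,
    params,
    doys,
    trait,
    noise_fraction=0.0,
    seed=0,
    series_id="s",
    reproductive_type=None,
):
    """Build a TraitSeries sampled from a growth family, optionally noisy."""
    clean = evaluate(family, params, doys)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_fraction * clean.max(), size=len(doys))
    if reproductive_type is None:
        reproductive_type = (
            "not_applicable" if trait == "rhizome_length" else "asexual"
        )
    return TraitSeries(
        series_id=series_id,
        patch_area_m2=1.0,
        trait=trait,
        reproductive_type=reproductive_type,
        doys=np.asarray(doys, dtype=float),
        increments=np.maximum(clean, 0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2021)


def random_valid_params(family, rng):
    """A random parameter draw satisfying the family invariants."""
    if family is ModelFamily.LOGISTIC:
        return LogisticParams(
            A1=0.0,
            A2=float(rng.uniform(20, 300)),
            x0=float(rng.uniform(80, 160)),
            p=float(rng.uniform(3, 20)),
        )
    if family is ModelFamily.BIHILL:
        ka = float(rng.uniform(90, 170))
        return BiHillParams(
            Pm=float(rng.uniform(50, 400)),
            Ka=ka,
            Ha=float(rng.uniform(3, 12)),
            Ki=float(ka * rng.uniform(1.5, 2.5)),
            Hi=float(rng.uniform(4, 12)),
        )
    l1 = float(rng.uniform(120, 190))
    return BiDoseRespParams(
        A1=0.0,
        A2=float(rng.uniform(50, 300)),
        L1=l1,
        L2=float(l1 + rng.uniform(60, 120)),
        h1=float(rng.uniform(0.03, 0.12)),
        h2=float(rng.uniform(0.03, 0.12)),
        P=float(rng.uniform(0.3, 0.8)),
    )
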