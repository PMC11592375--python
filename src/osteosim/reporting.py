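"""Bone-volume-fraction estimators and tissue reports.

Three descriptions of the simulated bone volume over the healing region:

* tissue proportion — the volume-weighted mean bone fraction;
* tissue-fraction threshold — an element whose bone fraction reaches 0.25
  counts as fully bone, the rest contribute their bone fraction;
* elastic-modulus threshold — an element whose homogenized modulus reaches
  10 MPa counts as fully bone, the rest contribute their bone fraction.

The threshold descriptions mimic how micro-CT segmentation saturates
maturing elements, so both bound the proportion estimate from below never —
counting elements fully can only increase the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regulation import RegulationRuleSet, TISSUES, homogenize_material


def _check_region(volumes: np.ndarray) -> np.ndarray:
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0:
        raise ValueError("healing region is empty")
    if np.any(volumes <= 0):
        raise ValueError("element volumes must be positive")
    return volumes


def bone_fraction_proportion(compositions: np.ndarray, volumes: np.ndarray) -> float:
    """Volume-weighted mean bone fraction over the healing region."""
    comp = np.atleast_2d(np.asarray(compositions, dtype=float))
    volumes = _check_region(volumes)
    return float(np.sum(volumes * comp[:, 3]) / volumes.sum())


def bone_fraction_threshold(
    compositions: np.ndarray, volumes: np.ndarray, threshold: float = 0.25
) -> float:
    """Tissue-fraction-threshold bone volume fraction.

    Elements with bone fraction >= ``threshold`` contribute their whole
    volume; the remainder contribute their bone share.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    comp = np.atleast_2d(np.asarray(compositions, dtype=float))
    volumes = _check_region(volumes)
    full = comp[:, 3] >= threshold
    v_bone = volumes[full].sum() + np.sum(volumes[~full] * comp[~full, 3])
    return float(v_bone / volumes.sum())


def bone_fraction_modulus(
    compositions: np.ndarray,
    volumes: np.ndarray,
    moduli: np.ndarray | None = None,
    threshold_mpa: float = 10.0,
    rules: RegulationRuleSet | None = None,
) -> float:
    """Elastic-modulus-threshold bone volume fraction.

    ``moduli`` are the homogenized element moduli; recomputed from the
    compositions by the rule of mixtures when omitted.
    """
    if not threshold_mpa > 0:
        raise ValueError(f"modulus threshold must be positive, got {threshold_mpa}")
    comp = np.atleast_2d(np.asarray(compositions, dtype=float))
    volumes = _check_region(volumes)
    if moduli is None:
        moduli, _ = homogenize_material(comp, rules)
    moduli = np.atleast_1d(np.asarray(moduli, dtype=float))
    full = moduli >= threshold_mpa
    v_bone = volumes[full].sum() + np.sum(volumes[~full] * comp[~full, 3])
    return float(v_bone / volumes.sum())


@dataclass
class VolumeFractionReport:
    """Four-tissue volume fractions under the three descriptions.

    Each row of ``table`` sums to 1: the thresholded descriptions reassign
    an above-threshold element's whole volume to bone and drop its non-bone
    share, keeping the total healing volume unchanged.
    """

    proportion: dict
    fraction_threshold: dict
    modulus_threshold: dict
    n_elements: int
    n_above_fraction_threshold: int
    n_above_modulus_threshold: int
    element_volume: float
    bone_indicator_fraction: np.ndarray = field(repr=False, default=None)
    bone_indicator_modulus: np.ndarray = field(repr=False, default=None)

    def as_table(self) -> dict:
        return {
            "proportion": self.proportion,
            "fraction_threshold": self.fraction_threshold,
            "modulus_threshold": self.modulus_threshold,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.as_table()).T[list(TISSUES)]


def _four_tissue_shares(
    comp: np.ndarray, volumes: np.ndarray, full: np.ndarray
) -> dict:
    """Per-tissue volume fractions with ``full`` elements counted as bone."""
    total = volumes.sum()
    shares = {}
    for idx, tissue in enumerate(TISSUES):
        v = np.sum(volumes[~full] * comp[~full, idx])
        if tissue == "bone":
            v += volumes[full].sum()
        shares[tissue] = float(v / total)
    return shares


def tissue_report(
    compositions: np.ndarray,
    volumes: np.ndarray | float = 1.0,
    moduli: np.ndarray | None = None,
    rules: RegulationRuleSet | None = None,
) -> VolumeFractionReport:
    """Full three-description, four-tissue report over the healing region."""
    r = rules if rules is not None else RegulationRuleSet()
    comp = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.isscalar(volumes):
        volumes = np.full(comp.shape[0], float(volumes))
    volumes = _check_region(volumes)
    if moduli is None:
        moduli, _ = homogenize_material(comp, r)
    moduli = np.atleast_1d(np.asarray(moduli, dtype=float))

    none_full = np.zeros(comp.shape[0], dtype=bool)
    full_frac = comp[:, 3] >= r.report_bone_fraction_threshold
    full_mod = moduli >= r.report_modulus_threshold_mpa

    return VolumeFractionReport(
        proportion=_four_tissue_shares(comp, volumes, none_full),
        fraction_threshold=_four_tissue_shares(comp, volumes, full_frac),
        modulus_threshold=_four_tissue_shares(comp, volumes, full_mod),
        n_elements=comp.shape[0],
        n_above_fraction_threshold=int(full_frac.sum()),
        n_above_modulus_threshold=int(full_mod.sum()),
        element_volume=float(np.mean(volumes)),
        bone_indicator_fraction=full_frac,
        bone_indicator_modulus=full_mod,
    )
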