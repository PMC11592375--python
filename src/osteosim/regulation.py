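"""Strain-driven tissue differentiation in the scaffold healing region.

Each healing-region element carries a four-phase tissue composition
(granulation, fibrous, cartilage, bone) that evolves iteratively: the voxel
elasticity problem is solved, the octahedral shear strain eps_d and
hydrostatic strain eps_H of every healing element are extracted, a
differentiation event is classified from rule windows in the (eps_H, eps_d)
plane, the composition is updated at the event's rate, and the element's
material is re-homogenized by a rule of mixtures. Iteration stops when the
bone volume fraction, sampled every 10 iterations, changes by less than 5%
relative (after a minimum number of iterations).

Strain window thresholds are expressed in percent strain throughout, as is
conventional for mechano-regulation rule tables.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import (
    ElementStrainState,
    LoadCase,
    MaterialField,
    RecycledCholeskySolver,
    VoxelFEModel,
    compute_element_strains,
    solve_system,
)
from .geometry import RegionLabel, VoxelModel

TISSUES = ("granulation", "fibrous", "cartilage", "bone")


class Event(enum.IntEnum):
    """Differentiation events, in classification priority order."""

    NONE = 0
    DESTRUCTION = 1
    FIBROUS = 2
    CARTILAGE = 3
    ENDOCHONDRAL = 4
    INTRAMEMBRANOUS = 5
    RESORPTION = 6


@dataclass
class TissueProperties:
    """Elastic constants of one tissue phenotype (E in MPa)."""

    E: float
    nu: float


@dataclass
class RegulationRuleSet:
    """Thresholds, rates and tissue properties of the differentiation rules.

    Strain windows are in percent strain. The destruction event fires at
    excessive stimulus; fibrous, cartilage and the two ossification events
    occupy windows of moderate stimulus; resorption fires near zero
    stimulus. Ossification additionally requires vascularized tissue and a
    face-adjacent neighbour whose bone fraction exceeds
    ``neighbor_bone_threshold`` (bone endplates and side bone count as bone),
    so bone growth is seeded from the surrounding bone.
    """

    # destruction: eps_H > 5 OR eps_d > 15 (percent)
    destruction_eH: float = 5.0
    destruction_ed: float = 15.0
    # fibrous: (-1 < eH < 5 AND 5 < ed < 15) OR (1 < eH < 5 AND ed < 15)
    fibrous_eH_lo: float = -1.0
    fibrous_eH_hi: float = 5.0
    fibrous_ed_lo: float = 5.0
    fibrous_ed_hi: float = 15.0
    fibrous_alt_eH_lo: float = 1.0
    # cartilage: -5 < eH < -1 AND 5 < ed < 15
    cartilage_eH_lo: float = -5.0
    cartilage_eH_hi: float = -1.0
    # endochondral: -5 < eH < -0.1 AND ed < 5
    endochondral_eH_lo: float = -5.0
    endochondral_eH_hi: float = -0.1
    endochondral_ed_hi: float = 5.0
    # intramembranous: (-0.1 < eH < 1 AND 1 < ed < 5) OR (0.1 < eH < 1 AND ed < 1)
    intramembranous_eH_lo: float = -0.1
    intramembranous_eH_hi: float = 1.0
    intramembranous_ed_lo: float = 1.0
    intramembranous_ed_hi: float = 5.0
    intramembranous_alt_eH_lo: float = 0.1
    # resorption: -0.1 < eH < 0.1 AND ed < 1
    resorption_eH: float = 0.1
    resorption_ed: float = 1.0

    # rates (volumetric transfer per iteration)
    rate_fibrous: float = 0.2
    rate_cartilage: float = 0.1
    rate_endochondral: float = 0.1  # times current cartilage fraction
    rate_intramembranous: float = 0.1
    rate_resorption: float = 0.05  # times current bone fraction

    # additional-rule thresholds (fractions)
    neighbor_bone_threshold: float = 0.25
    cartilage_fraction_threshold: float = 0.25
    bone_fraction_threshold: float = 0.75

    # tissue elastic properties
    tissue_properties: dict = field(
        default_factory=lambda: {
            "granulation": TissueProperties(0.2, 0.167),
            "fibrous": TissueProperties(2.0, 0.167),
            "cartilage": TissueProperties(10.0, 0.167),
            "bone": TissueProperties(1000.0, 0.325),
        }
    )

    # non-regulated region properties
    region_properties: dict = field(
        default_factory=lambda: {
            "SCAFFOLD": TissueProperties(1000.0, 0.2),
            "ENDPLATE_TOP": TissueProperties(10000.0, 0.325),
            "ENDPLATE_BOTTOM": TissueProperties(10000.0, 0.325),
            "SIDE_BONE": TissueProperties(0.01, 0.325),
        }
    )

    # convergence / reporting
    convergence_rel_change: float = 0.05
    convergence_sample_stride: int = 10
    min_iterations: int = 150
    max_iterations: int = 500
    report_bone_fraction_threshold: float = 0.25
    report_modulus_threshold_mpa: float = 10.0

    #: strictly positive floor on the homogenized modulus (MPa)
    modulus_floor: float = 0.2e-3

    def __post_init__(self) -> None:
        for name, rate in (
            ("rate_fibrous", self.rate_fibrous),
            ("rate_cartilage", self.rate_cartilage),
            ("rate_endochondral", self.rate_endochondral),
            ("rate_intramembranous", self.rate_intramembranous),
            ("rate_resorption", self.rate_resorption),
        ):
            if not 0.0 < rate <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {rate}")
        windows = (
            (self.fibrous_eH_lo, self.fibrous_eH_hi),
            (self.cartilage_eH_lo, self.cartilage_eH_hi),
            (self.endochondral_eH_lo, self.endochondral_eH_hi),
            (self.intramembranous_eH_lo, self.intramembranous_eH_hi),
            (self.fibrous_ed_lo, self.fibrous_ed_hi),
            (self.intramembranous_ed_lo, self.intramembranous_ed_hi),
        )
        for lo, hi in windows:
            if not lo < hi:
                raise ValueError(f"ill-ordered strain window ({lo}, {hi})")


@dataclass
class TissueComposition:
    """Volumetric tissue fractions of the healing elements, rows summing to 1."""

    fractions: np.ndarray  # (n_healing, 4) columns: gran, fib, cart, bone

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != 4:
            raise ValueError("fractions must have shape (n, 4)")
        self.validate()

    def validate(self, atol: float = 1e-12) -> None:
        f = self.fractions
        if np.any((f < -atol) | (f > 1 + atol)):
            raise ValueError("tissue fractions must lie in [0, 1]")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("tissue fractions must sum to 1 per element")

    @classmethod
    def granulation(cls, n: int) -> "TissueComposition":
        f = np.zeros((n, 4))
        f[:, 0] = 1.0
        return cls(f)

    @property
    def m_gran(self) -> np.ndarray:
        return self.fractions[:, 0]

    @property
    def m_fib(self) -> np.ndarray:
        return self.fractions[:, 1]

    @property
    def m_cart(self) -> np.ndarray:
        return self.fractions[:, 2]

    @property
    def m_bone(self) -> np.ndarray:
        return self.fractions[:, 3]


@dataclass
class SimulationTrace:
    """Per-iteration history of a regeneration run."""

    tissue_fractions: np.ndarray  # (n_iter, 4) volume-weighted means
    event_counts: np.ndarray  # (n_iter, 7) counts per Event value
    bone_samples: list  # vf_bone sampled every `stride` iterations
    converged: bool
    stop_iteration: int


# ---------------------------------------------------------------------------
# Stimuli


def octahedral_shear_strain(e1, e2, e3):
    """eps_d = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e1-e3)^2); permutation-invariant, >= 0."""
    e1, e2, e3 = (np.asarray(e, dtype=float) for e in (e1, e2, e3))
    return (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e1 - e3) ** 2)


def hydrostatic_strain(e1, e2, e3):
    """eps_H = (e1 + e2 + e3) / 3; signed, negative under net compression."""
    e1, e2, e3 = (np.asarray(e, dtype=float) for e in (e1, e2, e3))
    return (e1 + e2 + e3) / 3.0


def stimuli_percent(strains: ElementStrainState) -> tuple[np.ndarray, np.ndarray]:
    """(eps_H, eps_d) per element in percent strain."""
    p = strains.principal
    eH = hydrostatic_strain(p[:, 0], p[:, 1], p[:, 2]) * 100.0
    ed = octahedral_shear_strain(p[:, 0], p[:, 1], p[:, 2]) * 100.0
    return eH, ed


# ---------------------------------------------------------------------------
# Event classification and application


def classify_event(
    eH,
    ed,
    composition: np.ndarray,
    neighbor_bone_ok,
    vascularized=True,
    rules: RegulationRuleSet | None = None,
):
    """Differentiation event per element from percent-strain stimuli.

    ``composition`` is (n, 4); flags broadcast. Events are tested in priority
    order destruction -> fibrous -> cartilage -> endochondral ->
    intramembranous -> resorption; stimuli outside every window yield NONE
    (the rule table is exhaustive of events, not of the strain plane).
    """
    r = rules if rules is not None else RegulationRuleSet()
    eH = np.atleast_1d(np.asarray(eH, dtype=float))
    ed = np.atleast_1d(np.asarray(ed, dtype=float))
    comp = np.atleast_2d(np.asarray(composition, dtype=float))
    m_cart, m_bone = comp[:, 2], comp[:, 3]
    nb = np.broadcast_to(np.asarray(neighbor_bone_ok, dtype=bool), eH.shape)
    vasc = np.broadcast_to(np.asarray(vascularized, dtype=bool), eH.shape)

    destruction = (eH > r.destruction_eH) | (ed > r.destruction_ed)
    fibrous = (
        (r.fibrous_eH_lo < eH)
        & (eH < r.fibrous_eH_hi)
        & (r.fibrous_ed_lo < ed)
        & (ed < r.fibrous_ed_hi)
    ) | (
        (r.fibrous_alt_eH_lo < eH) & (eH < r.fibrous_eH_hi) & (ed < r.fibrous_ed_hi)
    )
    cartilage = (
        (r.cartilage_eH_lo < eH)
        & (eH < r.cartilage_eH_hi)
        & (r.fibrous_ed_lo < ed)
        & (ed < r.fibrous_ed_hi)
        & (m_cart < r.cartilage_fraction_threshold)
        & (m_bone < r.bone_fraction_threshold)
    )
    endochondral = (
        (r.endochondral_eH_lo < eH)
        & (eH < r.endochondral_eH_hi)
        & (ed < r.endochondral_ed_hi)
        & vasc
        & nb
        & (m_cart > r.cartilage_fraction_threshold)
    )
    intramembranous = (
        (
            (r.intramembranous_eH_lo < eH)
            & (eH < r.intramembranous_eH_hi)
            & (r.intramembranous_ed_lo < ed)
            & (ed < r.intramembranous_ed_hi)
        )
        | (
            (r.intramembranous_alt_eH_lo < eH)
            & (eH < r.intramembranous_eH_hi)
            & (ed < r.intramembranous_ed_lo)
        )
    ) & vasc & nb & (m_cart < r.cartilage_fraction_threshold)
    resorption = (
        (-r.resorption_eH < eH) & (eH < r.resorption_eH) & (ed < r.resorption_ed)
    )

    events = np.select(
        [destruction, fibrous, cartilage, endochondral, intramembranous, resorption],
        [
            Event.DESTRUCTION,
            Event.FIBROUS,
            Event.CARTILAGE,
            Event.ENDOCHONDRAL,
            Event.INTRAMEMBRANOUS,
            Event.RESORPTION,
        ],
        default=Event.NONE,
    )
    return events if events.shape != (1,) else Event(int(events[0]))


def apply_event(
    composition: np.ndarray, events, rules: RegulationRuleSet | None = None
) -> np.ndarray:
    """Update tissue fractions by the classified events (vectorized).

    Flat-rate formation events transfer from granulation, clamped to its
    availability; endochondral ossification converts a fixed share of the
    current cartilage to bone, resorption returns a share of the current
    bone to granulation; destruction resets the element to pure granulation.
    The four fractions sum to 1 afterwards.
    """
    r = rules if rules is not None else RegulationRuleSet()
    comp = np.atleast_2d(np.array(composition, dtype=float, copy=True))
    ev = np.broadcast_to(np.atleast_1d(np.asarray(events, dtype=int)), comp.shape[:1])

    m = ev == Event.DESTRUCTION
    comp[m] = (1.0, 0.0, 0.0, 0.0)

    for event, col, rate in (
        (Event.FIBROUS, 1, r.rate_fibrous),
        (Event.CARTILAGE, 2, r.rate_cartilage),
        (Event.INTRAMEMBRANOUS, 3, r.rate_intramembranous),
    ):
        m = ev == event
        dm = np.minimum(rate, comp[m, 0])
        comp[m, 0] -= dm
        comp[m, col] += dm

    m = ev == Event.ENDOCHONDRAL
    dm = r.rate_endochondral * comp[m, 2]
    comp[m, 2] -= dm
    comp[m, 3] += dm

    m = ev == Event.RESORPTION
    dm = r.rate_resorption * comp[m, 3]
    comp[m, 3] -= dm
    comp[m, 0] += dm

    # renormalize away accumulated round-off so the mass qualifier is exact
    comp /= comp.sum(axis=1, keepdims=True)
    return comp if np.asarray(composition).ndim == 2 else comp[0]


def homogenize_material(
    composition: np.ndarray, rules: RegulationRuleSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rule-of-mixtures element properties from the tissue fractions.

    The modulus mixes with cubic weights, E = sum_t E_t m_t^3 (penalizing
    dilute stiff phases); the Poisson ratio mixes linearly. A strictly
    positive floor guards degenerate stiffness when all fractions are small.
    """
    r = rules if rules is not None else RegulationRuleSet()
    comp = np.atleast_2d(np.asarray(composition, dtype=float))
    Es = np.array([r.tissue_properties[t].E for t in TISSUES])
    nus = np.array([r.tissue_properties[t].nu for t in TISSUES])
    E = (comp**3) @ Es
    nu = comp @ nus
    E = np.maximum(E, r.modulus_floor)
    if np.asarray(composition).ndim == 1:
        return float(E[0]), float(nu[0])
    return E, nu


# ---------------------------------------------------------------------------
# Convergence


def check_convergence(
    bone_samples,
    rules: RegulationRuleSet | None = None,
    iteration: int | None = None,
) -> bool:
    """Steady-state test on bone volume fraction sampled every 10 iterations.

    Converged when |vf_k+1 - vf_k| / vf_k+1 < 0.05 between the last two
    samples (zero change of a zero fraction also converges) and the
    minimum-iteration floor has been passed.
    """
    r = rules if rules is not None else RegulationRuleSet()
    if iteration is not None and iteration < r.min_iterations:
        return False
    if len(bone_samples) < 2:
        return False
    prev, cur = bone_samples[-2], bone_samples[-1]
    if cur == 0.0:
        return prev == 0.0
    return abs(cur - prev) / abs(cur) < r.convergence_rel_change


# ---------------------------------------------------------------------------
# The iterative algorithm


class RegenerationSimulator:
    """Iterative mechano-regulated tissue regeneration on a voxel model.

    Wires the elasticity solve, stimulus extraction, event classification,
    composition update and material homogenization into the iteration loop.
    Deterministic: identical configurations produce bitwise-identical traces.
    """

    def __init__(
        self,
        model: VoxelModel,
        rules: RegulationRuleSet | None = None,
        load: LoadCase | None = None,
        solver: str = "auto",
    ):
        self.model = model
        self.rules = rules if rules is not None else RegulationRuleSet()
        self.load = load if load is not None else LoadCase()
        self.fe = VoxelFEModel(model)
        active = model.active_mask
        lab_active = model.labels[active]
        self.healing_sel = lab_active == RegionLabel.HEALING
        self.n_healing = int(self.healing_sel.sum())
        if self.n_healing == 0:
            raise ValueError("model has no healing region to regulate")
        self.solver = solver

        # fixed materials of the non-regulated regions
        E = np.empty(self.fe.n_elements)
        nu = np.empty(self.fe.n_elements)
        for name, props in self.rules.region_properties.items():
            sel = lab_active == RegionLabel[name]
            E[sel], nu[sel] = props.E, props.nu
        gran = self.rules.tissue_properties["granulation"]
        E[self.healing_sel], nu[self.healing_sel] = gran.E, gran.nu
        self._E0, self._nu0 = E, nu

        # healing-voxel bookkeeping for the neighbour-bone rule
        self._healing_ijk = np.stack(
            np.nonzero(model.labels == RegionLabel.HEALING), axis=1
        )
        self._bone_grid = np.zeros(model.labels.shape)
        # endplates and side bone count as fully bone when seeding ossification
        seed = (
            (model.labels == RegionLabel.ENDPLATE_TOP)
            | (model.labels == RegionLabel.ENDPLATE_BOTTOM)
            | (model.labels == RegionLabel.SIDE_BONE)
        )
        self._seed_grid = seed

        self._fixed, self._f = self.fe.boundary_conditions(self.load)
        static = ~self.healing_sel
        self.fe.cache_static_elements(static, MaterialField(self._E0, self._nu0))
        if solver == "auto":
            solver = "recycled" if self.fe.n_dofs > 20000 else "direct"
        self._solver_kind = solver
        self._recycled = (
            RecycledCholeskySolver(self.fe, self._fixed, rtol=1e-5)
            if solver == "recycled"
            else None
        )

    # -- helpers -----------------------------------------------------------

    def materials_for(self, composition: TissueComposition) -> MaterialField:
        E = self._E0.copy()
        nu = self._nu0.copy()
        Eh, nuh = homogenize_material(composition.fractions, self.rules)
        E[self.healing_sel] = Eh
        nu[self.healing_sel] = nuh
        return MaterialField(E, nu)

    def neighbor_bone_ok(self, composition: TissueComposition) -> np.ndarray:
        """Any face-adjacent neighbour with bone fraction above threshold."""
        grid = np.where(self._seed_grid, 1.0, 0.0)
        ijk = self._healing_ijk
        grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = composition.m_bone
        thr = self.rules.neighbor_bone_threshold
        over = grid > thr
        nb = np.zeros_like(over)
        for axis in range(3):
            lo = np.zeros_like(over)
            hi = np.zeros_like(over)
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(1, None)
            sl_b[axis] = slice(None, -1)
            lo[tuple(sl_a)] = over[tuple(sl_b)]
            hi[tuple(sl_b)] = over[tuple(sl_a)]
            nb |= lo | hi
        return nb[ijk[:, 0], ijk[:, 1], ijk[:, 2]]

    def healing_stimuli(self, materials: MaterialField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Solve elasticity and return (eps_H%, eps_d%, displacements)."""
        K = self.fe.assemble(materials)
        if self._recycled is not None:
            u = self._recycled.solve(K, self._f)
        else:
            u = solve_system(K, self._f, self._fixed, solver="direct")
        strains = compute_element_strains(self.fe, u, subset=self.healing_sel)
        eH, ed = stimuli_percent(strains)
        return eH, ed, u

    # -- main loop ---------------------------------------------------------

    def run(
        self,
        composition: TissueComposition | None = None,
        max_iterations: int | None = None,
        progress: bool = False,
    ):
        """Iterate to Eq.-9-style steady state; returns (trace, final_state).

        ``final_state`` is a dict with the final composition, homogenized
        materials, last stimuli and displacement field.
        """
        r = self.rules
        cap = max_iterations if max_iterations is not None else r.max_iterations
        comp = (
            composition
            if composition is not None
            else TissueComposition.granulation(self.n_healing)
        )
        fractions_log = []
        events_log = []
        bone_samples: list[float] = []
        converged = False
        iteration = 0
        eH = ed = None
        materials = self.materials_for(comp)
        u = None
        for iteration in range(1, cap + 1):
            eH, ed, u = self.healing_stimuli(materials)
            nb = self.neighbor_bone_ok(comp)
            events = classify_event(eH, ed, comp.fractions, nb, True, r)
            new_fractions = apply_event(comp.fractions, events, r)
            comp = TissueComposition(new_fractions)
            materials = self.materials_for(comp)

            fractions_log.append(comp.fractions.mean(axis=0))
            events_log.append(np.bincount(np.asarray(events, dtype=int).ravel(), minlength=7))
            if progress:
                fr = fractions_log[-1]
                extra = (
                    f" cg={self._recycled.last_cg_iters}"
                    f" nf={self._recycled.n_factorizations}"
                    if self._recycled is not None
                    else ""
                )
                print(
                    f"iter={iteration} gran={fr[0]:.4f} fib={fr[1]:.4f} "
                    f"cart={fr[2]:.4f} bone={fr[3]:.4f}{extra}"
                )
            if iteration % r.convergence_sample_stride == 0:
                bone_samples.append(float(comp.m_bone.mean()))
                if check_convergence(bone_samples, r, iteration):
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"regeneration did not reach steady state within {cap} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        trace = SimulationTrace(
            tissue_fractions=np.array(fractions_log),
            event_counts=np.array(events_log),
            bone_samples=bone_samples,
            converged=converged,
            stop_iteration=iteration,
        )
        Eh, nuh = homogenize_material(comp.fractions, r)
        final_state = {
            "composition": comp,
            "E_healing": np.atleast_1d(Eh),
            "nu_healing": np.atleast_1d(nuh),
            "eps_H_percent": eH,
            "eps_d_percent": ed,
            "displacements": u,
        }
        return trace, final_state


def run_simulation(model: VoxelModel, rules=None, load=None, **kwargs):
    """Convenience wrapper: build a simulator and run it."""
    sim = RegenerationSimulator(model, rules=rules, load=load)
    return sim.run(**kwargs)
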