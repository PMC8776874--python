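"""Synthetic phantom cohorts with known habitat and CEST ground truth.

Patient imaging of the kind this pipeline targets is not shareable, so
every stage is exercised on phantoms:

* **Habitat cohorts** — per subject, an ellipsoidal brain mask containing an
  ellipsoidal tumor partitioned into spatially contiguous habitat blobs
  (capacity-constrained seeded growth) whose proportions are drawn from an
  IDH-class-specific Dirichlet; voxel channel values are Gaussian around
  each habitat's 4-channel mean, background tissue around its own mean.
  Channel values are generated directly in normalized (z-score) space by
  default; a raw-scale mode applies a per-channel affine and per-subject
  offset to exercise the normalization stage.

* **CEST phantoms** — per-voxel z-spectra from an inverted-Lorentzian water
  line plus a planted amine pool at +3.0 ppm, optionally shifted by a B0
  field and degraded with Gaussian noise, with the noiseless MTRasym ground
  truth computed from the same band-average formula the pipeline uses.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning, so a cohort is reproducible bit-exactly from (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cest import (AMINE_OFFSET_PPM, DEFAULT_BAND_HALFWIDTH_PPM, MTRAsymMap,
                   ZSpectrumVolume, default_offsets, inverted_lorentzian)
from .features import IDH_MUTANT, IDH_WILDTYPE, N_CHANNELS, SubjectStack

logger = logging.getLogger(__name__)


@dataclass
class HabitatSpec:
    """Generator parameters for one phantom cohort.

    Habitat means live in normalized channel space (CE-T1WI, FLAIR,
    MTRasym, ADC) and are ordered by descending ADC: habitat 1 is the
    high-ADC, non-enhancing "mutant-like" tissue, the last habitats are the
    low-ADC / contrast-enhancing / acidic "wild-type-like" tissue, matching
    the pattern reported for gliomas.  The per-class Dirichlet
    concentrations (defaults (8,2,1,1) mutant, (1,1,6,6) wild-type) tie
    tumor composition to IDH class.
    """

    habitat_means: np.ndarray = field(default_factory=lambda: np.array([
        # ce_t1wi, flair, mtr_asym, adc
        [-1.5,  0.5, -1.0,  2.5],   # mutant-like: high ADC, no enhancement
        [-0.5, -1.0,  0.5,  0.5],   # intermediate
        [ 2.0,  0.5, -0.5, -1.0],   # wild-type-like: enhancing
        [ 0.5, -0.5,  2.0, -2.5],   # wild-type-like: acidic, high cellularity
    ]))
    habitat_sds: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.4))
    dirichlet_mutant: np.ndarray = field(default_factory=lambda: np.array([8.0, 2.0, 1.0, 1.0]))
    dirichlet_wildtype: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 6.0, 6.0]))
    shape: tuple[int, int, int] = (48, 48, 48)
    brain_axes_frac: tuple[float, float, float] = (0.42, 0.42, 0.42)
    tumor_axes_frac_range: tuple[float, float] = (0.14, 0.20)
    background_mean: np.ndarray = field(default_factory=lambda: np.zeros(4))
    background_sd: np.ndarray = field(default_factory=lambda: np.full(4, 0.3))
    raw_scale: bool = False  # emit un-normalized channels (affine + subject offset)

    def __post_init__(self) -> None:
        self.habitat_means = np.atleast_2d(np.asarray(self.habitat_means, dtype=float))
        self.habitat_sds = np.atleast_2d(np.asarray(self.habitat_sds, dtype=float))
        self.dirichlet_mutant = np.asarray(self.dirichlet_mutant, dtype=float)
        self.dirichlet_wildtype = np.asarray(self.dirichlet_wildtype, dtype=float)
        h = self.n_habitats
        if self.habitat_means.shape[1] != N_CHANNELS:
            raise ValueError("habitat means must have 4 channels")
        if self.habitat_sds.shape != self.habitat_means.shape:
            raise ValueError("habitat sds must match means shape")
        if len(self.dirichlet_mutant) != h or len(self.dirichlet_wildtype) != h:
            raise ValueError("Dirichlet concentration length must equal habitat count")
        if np.any(self.dirichlet_mutant <= 0) or np.any(self.dirichlet_wildtype <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        if np.any(self.habitat_sds <= 0):
            raise ValueError("habitat sds must be positive")

    @property
    def n_habitats(self) -> int:
        return len(self.habitat_means)

    def concentrations(self, idh_class: str) -> np.ndarray:
        return (self.dirichlet_mutant if idh_class == IDH_MUTANT
                else self.dirichlet_wildtype)


def null_spec(spec: HabitatSpec | None = None) -> HabitatSpec:
    """Copy of a spec with the class difference removed (equal Dirichlets)."""
    spec = spec if spec is not None else HabitatSpec()
    mixed = 0.5 * (spec.dirichlet_mutant + spec.dirichlet_wildtype)
    return replace(spec, dirichlet_mutant=mixed.copy(), dirichlet_wildtype=mixed.copy())


@dataclass
class SubjectTruth:
    """Ground truth for one phantom subject."""

    habitat_map: np.ndarray          # 0 outside tumor, 1..H inside
    drawn_proportions: np.ndarray    # the Dirichlet draw
    realized_proportions: np.ndarray


@dataclass
class PhantomCohort:
    stacks: list[SubjectStack]
    truths: list[SubjectTruth]
    seed: int
    spec: HabitatSpec

    def __len__(self) -> int:
        return len(self.stacks)


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)) <= 1.0


def _partition_tumor(coords: np.ndarray, proportions: np.ndarray,
                     rng: np.random.Generator, tol: float = 0.02) -> np.ndarray:
    """Partition tumor voxels into contiguous blobs matching proportions.

    Capacity-constrained weighted-Voronoi growth: habitat seed points are
    spread by farthest-point sampling, voxels go to the habitat minimizing
    (distance - weight), and the weights are iterated until each habitat's
    voxel share is within ``tol`` of its target; a final swap-based repair
    tightens stragglers.  Returns per-voxel habitat indices (0-based).
    """
    n, h = len(coords), len(proportions)
    if n < h:
        return rng.integers(0, h, size=n)
    # farthest-point seed spread, first seed random
    seeds = [int(rng.integers(n))]
    d_min = np.linalg.norm(coords - coords[seeds[0]], axis=1)
    for _ in range(h - 1):
        seeds.append(int(np.argmax(d_min)))
        d_min = np.minimum(d_min, np.linalg.norm(coords - coords[seeds[-1]], axis=1))
    D = np.stack([np.linalg.norm(coords - coords[s], axis=1) for s in seeds])  # (h, n)

    targets = proportions * n
    scale = (3.0 * n / (4.0 * np.pi)) ** (1.0 / 3.0)  # equivalent-sphere radius
    w = np.zeros(h)
    best_lab, best_err = None, np.inf
    for _ in range(300):
        lab = np.argmin(D - w[:, None], axis=0)
        counts = np.bincount(lab, minlength=h).astype(float)
        err = np.max(np.abs(counts - targets)) / n
        if err < best_err:
            best_lab, best_err = lab.copy(), err
            if err <= tol / 4:
                break
        w += (targets - counts) / n * scale * 0.5

    lab = best_lab
    if best_err > tol:  # greedy repair: move cheapest boundary voxels
        counts = np.bincount(lab, minlength=h).astype(float)
        for _ in range(int(n)):
            surplus = int(np.argmax(counts - targets))
            deficit = int(np.argmin(counts - targets))
            if (counts[surplus] - targets[surplus] <= tol * n
                    and targets[deficit] - counts[deficit] <= tol * n):
                break
            cand = np.flatnonzero(lab == surplus)
            move = cand[int(np.argmin(D[deficit, cand] - D[surplus, cand]))]
            lab[move] = deficit
            counts[surplus] -= 1
            counts[deficit] += 1
    return lab


def generate_subject(spec: HabitatSpec, idh_class: str, seed,
                     subject_id: str = "sim") -> tuple[SubjectStack, SubjectTruth]:
    """Generate one phantom subject and its ground truth.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if idh_class not in (IDH_MUTANT, IDH_WILDTYPE):
        raise ValueError(f"unknown IDH class {idh_class!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    shape = spec.shape
    center = np.array(shape, dtype=float) / 2.0
    brain_axes = np.array(spec.brain_axes_frac) * np.array(shape)
    brain = _ellipsoid_mask(shape, center, brain_axes)

    lo, hi = spec.tumor_axes_frac_range
    tumor_axes = rng.uniform(lo, hi, size=3) * np.array(shape)
    if np.any(tumor_axes > brain_axes):
        raise ValueError("tumor semi-axes exceed the brain mask")
    # offset the tumor center while keeping the tumor inside the brain ellipsoid
    slack = (brain_axes - tumor_axes) / np.sqrt(3.0)
    t_center = center + rng.uniform(-1.0, 1.0, size=3) * slack * 0.8
    tumor = _ellipsoid_mask(shape, t_center, tumor_axes) & brain
    if not tumor.any():
        raise ValueError("tumor mask is empty")

    props = rng.dirichlet(spec.concentrations(idh_class))
    coords = np.column_stack(np.nonzero(tumor)).astype(float)
    lab0 = _partition_tumor(coords, props, rng)

    habitat_map = np.zeros(shape, dtype=int)
    habitat_map[tumor] = lab0 + 1
    realized = np.bincount(lab0, minlength=spec.n_habitats) / len(lab0)

    channels = np.full((N_CHANNELS,) + shape, np.nan)
    n_brain = int(brain.sum())
    for c in range(N_CHANNELS):
        channels[c][brain] = (spec.background_mean[c]
                              + spec.background_sd[c] * rng.standard_normal(n_brain))
    for hidx in range(spec.n_habitats):
        sel = habitat_map == hidx + 1
        nsel = int(sel.sum())
        for c in range(N_CHANNELS):
            channels[c][sel] = (spec.habitat_means[hidx, c]
                                + spec.habitat_sds[hidx, c] * rng.standard_normal(nsel))
    if spec.raw_scale:
        # per-channel affine plus a per-subject offset, to exercise z-scoring
        gains = np.array([600.0, 400.0, 0.05, 0.8e-3])
        offsets = np.array([1500.0, 1200.0, 0.02, 1.1e-3])
        subj_shift = rng.normal(0.0, 0.1, size=N_CHANNELS)
        for c in range(N_CHANNELS):
            channels[c] = (channels[c] + subj_shift[c]) * gains[c] + offsets[c]

    stack = SubjectStack(subject_id=subject_id, channels=channels,
                         brain_mask=brain, tumor_mask=tumor,
                         idh_status=idh_class,
                         age=float(np.round(rng.uniform(19, 80), 1)),
                         metadata={"synthetic": True, "raw_scale": spec.raw_scale})
    return stack, SubjectTruth(habitat_map, props, realized)


def generate_cohort(spec: HabitatSpec, n_mutant: int = 32, n_wildtype: int = 37,
                    seed: int = 0) -> PhantomCohort:
    """Generate an IDH-labeled phantom cohort (defaults echo a 32/37 split).

    Each subject gets an independent child seed spawned from the master
    seed, so the cohort is bit-reproducible and subjects are independent.
    """
    if n_mutant < 1 or n_wildtype < 1:
        raise ValueError("need >= 1 subject per class")
    children = np.random.SeedSequence(seed).spawn(n_mutant + n_wildtype)
    stacks, truths = [], []
    classes = [IDH_MUTANT] * n_mutant + [IDH_WILDTYPE] * n_wildtype
    for i, (cls, child) in enumerate(zip(classes, children)):
        stack, truth = generate_subject(spec, cls, child, subject_id=f"sub-{i:03d}")
        stacks.append(stack)
        truths.append(truth)
    return PhantomCohort(stacks, truths, seed, spec)


# ---------------------------------------------------------------------------
# CEST phantom

WATER_AMPLITUDE = 0.85
WATER_GAMMA_PPM = 1.0
AMINE_GAMMA_PPM = 0.5


def cest_model(offsets: np.ndarray, asym_amplitude: float,
               delta: float = 0.0) -> np.ndarray:
    """Noiseless normalized z-spectrum: water line plus planted amine pool.

    S(omega)/S0 = 1 - L(omega - delta; A_w, Gamma_w)
                    - a * L(omega - delta - 3.0; 1, Gamma_a)
    """
    water = 1.0 - inverted_lorentzian(offsets, WATER_AMPLITUDE, WATER_GAMMA_PPM, delta)
    amine = asym_amplitude * (1.0 - inverted_lorentzian(
        offsets, 1.0, AMINE_GAMMA_PPM, delta + AMINE_OFFSET_PPM))
    return 1.0 - water - amine


def analytic_mtr_asym(offsets: np.ndarray, asym_amplitude: float,
                      band_halfwidth_ppm: float = DEFAULT_BAND_HALFWIDTH_PPM) -> float:
    """Band-average MTRasym of the noiseless, unshifted phantom model."""
    z = cest_model(offsets, asym_amplitude, delta=0.0)
    neg = np.abs(offsets + AMINE_OFFSET_PPM) <= band_halfwidth_ppm + 1e-9
    pos = np.abs(offsets - AMINE_OFFSET_PPM) <= band_halfwidth_ppm + 1e-9
    return float(z[neg].mean() - z[pos].mean())


def generate_cest_phantom(asym_amplitude: float = 0.03,
                          b0_field: np.ndarray | float = 0.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          shape: tuple[int, int, int] = (16, 16, 4),
                          offsets: np.ndarray | None = None,
                          s0_value: float = 1000.0,
                          ) -> tuple[ZSpectrumVolume, MTRAsymMap]:
    """Generate a CEST z-spectrum phantom and its true MTRasym map.

    ``b0_field`` is a per-voxel shift volume (ppm) or a scalar applied
    uniformly; ``asym_amplitude`` sets the planted amine asymmetry.  The
    returned truth map holds the analytic band-average MTRasym of the
    noiseless, unshifted model (identical at every voxel).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    offsets = default_offsets() if offsets is None else np.asarray(offsets, dtype=float)
    if np.isscalar(b0_field):
        b0 = np.full(shape, float(b0_field))
    else:
        b0 = np.asarray(b0_field, dtype=float)
        shape = b0.shape
    span = offsets.max() - offsets.min()
    if np.nanmax(np.abs(b0)) > span / 2:
        raise ValueError("offset grid too sparse for the requested B0 range")

    rng = np.random.default_rng(seed)
    z = cest_model(offsets[None, None, None, :], asym_amplitude, b0[..., None])
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    mask = np.ones(shape, dtype=bool)
    zspec = ZSpectrumVolume(signal=z * s0_value, offsets_ppm=offsets,
                            s0=np.full(shape, s0_value), mask=mask)
    truth_val = analytic_mtr_asym(offsets, asym_amplitude)
    truth = MTRAsymMap(np.full(shape, truth_val), mask.copy())
    return zspec, truth
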