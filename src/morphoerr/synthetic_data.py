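"""Synthetic replicated landmark studies with planted variance components.

Emulates a replicated data-acquisition design for 2D landmark data: several
species groups of individuals, each individual digitised under every
combination of 2 imaging devices x 2 observers x 2 digitising trials (eight
replicate datasets), plus one "tilted" presentation set in which the latent
3D configuration is rotated out of plane before orthographic projection, and
a set of unknown specimens drawn from a species mixture.

Device and observer effects are systematic: a single Gaussian landmark
displacement field is drawn per device and per observer and added to every
specimen measured under that source.  Digitising (session) noise is redrawn
per record.  This reproduces the qualitative distinction between systematic
instrument/personnel error and random digitising error; it does not model
lens distortion, pixelation, or correlated landmark placement errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmark_io import AcquisitionLabel, LandmarkConfiguration, LandmarkDataset

__all__ = ["StudySpec", "SimulatedStudy", "make_template", "project_tilted",
           "simulate_study"]


@dataclass(frozen=True)
class StudySpec:
    """Generator parameters for one synthetic landmark study.

    All displacement scales are per-coordinate Gaussian standard deviations
    on a template normalised to unit centroid size (so an sd of 0.02 moves a
    landmark by roughly 10% of the mean landmark-to-centroid distance of a
    21-point shape).  The defaults plant the variance ordering
    individuals > interobserver > intraobserver(session) > device, with
    species-level separation comparable to device error — the regime of
    closely related, morphologically similar groups where acquisition error
    competes with the biological signal.
    """

    n_species: int = 5
    n_per_species: int = 50
    k: int = 21
    species_effect_sd: float = 0.008
    individual_sd: float = 0.02
    device_bias_sd: float = 0.008
    observer_bias_sd: float = 0.017
    session_noise_sd: float = 0.0125
    relief_sd: float = 0.05
    tilt_range_deg: tuple[float, float] = (5.0, 20.0)
    n_unknowns: int = 31
    unknown_mixture: tuple[float, ...] = (0.48, 0.13, 0.13, 0.13, 0.13)
    devices: tuple[str, str] = ("Dinolite", "Nikon")
    observers: tuple[str, str] = ("EO", "NO")
    n_trials: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("species_effect_sd", "individual_sd", "device_bias_sd",
                     "observer_bias_sd", "session_noise_sd", "relief_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.unknown_mixture) != self.n_species:
            raise ValueError("unknown_mixture must have one proportion per species")
        if abs(sum(self.unknown_mixture) - 1.0) > 1e-8:
            raise ValueError("unknown_mixture must sum to 1")
        if self.n_per_species < 3:
            raise ValueError("n_per_species must be >= 3 (LOOCV needs 3 per group)")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


def make_template(k: int = 21, seed: int = 0, relief_sd: float = 0.05) -> LandmarkConfiguration:
    """Reproducible closed-outline template with latent z relief.

    Landmarks sit on a smoothly perturbed, elongated closed outline (a
    stand-in for a molar occlusal margin), normalised so the 2D part is
    centered at the origin with unit centroid size; z is drawn at
    ``relief_sd`` and centered.
    """
    if k < 3:
        raise ValueError("template needs k >= 3")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    radius = np.ones(k)
    for h in range(2, 5):
        a, b = rng.normal(0.0, 0.25 / h, size=2)
        radius += a * np.cos(h * t) + b * np.sin(h * t)
    radius = np.clip(radius, 0.3, None)
    xy = np.column_stack([0.6 * radius * np.cos(t), radius * np.sin(t)])
    xy -= xy.mean(axis=0)
    xy /= np.sqrt((xy**2).sum())
    z = rng.normal(0.0, relief_sd, size=k) if relief_sd > 0 else np.zeros(k)
    z -= z.mean()
    return LandmarkConfiguration("template", np.column_stack([xy, z]))


def project_tilted(config: LandmarkConfiguration, tilt_x_deg: float,
                   tilt_y_deg: float) -> LandmarkConfiguration:
    """Rotate a 3D configuration about the in-plane axes, then drop z.

    Rotation about the x axis by ``tilt_x_deg`` followed by rotation about
    the y axis by ``tilt_y_deg``, then orthographic projection onto the
    image plane.  A planar configuration tilted about one axis simply has
    the perpendicular coordinate scaled by the cosine of the angle.
    """
    coords = config.coords
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    ax = np.deg2rad(tilt_x_deg)
    ay = np.deg2rad(tilt_y_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rotated = coords @ rx.T @ ry.T
    return LandmarkConfiguration(config.specimen_id, rotated[:, :2])


@dataclass
class SimulatedStudy:
    """Nine replicate datasets, unknowns, and the generative truth record."""

    spec: StudySpec
    datasets: dict[str, LandmarkDataset]
    unknowns: LandmarkDataset
    truth: pd.DataFrame                    # specimen_id, true_species (unknowns)
    template: LandmarkConfiguration
    species_means: np.ndarray = field(repr=False, default=None)  # (s, k, 2)

    @property
    def tilted_name(self) -> str:
        return AcquisitionLabel(self.spec.devices[0], True, self.spec.observers[0], 1).name

    def replicate_names(self) -> list[str]:
        return [n for n in self.datasets if not self.datasets[n].label.tilted]


def simulate_study(spec: StudySpec) -> SimulatedStudy:
    """Generate the full replicated study implied by ``spec``.

    Per species: mean shape = template + species displacement field.  Per
    individual: species mean + individual field.  Per record: individual
    shape + device bias + observer bias + fresh session noise; the tilted
    presentation set additionally rotates each individual's latent 3D shape
    by angles drawn from ``tilt_range_deg`` (random sign, per axis) before
    projection.  All randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    template = make_template(spec.k, seed=int(rng.integers(2**31)),
                             relief_sd=spec.relief_sd)
    base2d = template.xy
    z = template.coords[:, 2]
    k = spec.k
    species = spec.species_names

    species_eff = rng.normal(0.0, spec.species_effect_sd, size=(spec.n_species, k, 2)) \
        if spec.species_effect_sd > 0 else np.zeros((spec.n_species, k, 2))
    species_means = base2d + species_eff

    n_ind = spec.n_species * spec.n_per_species
    ind_eff = rng.normal(0.0, spec.individual_sd, size=(n_ind, k, 2)) \
        if spec.individual_sd > 0 else np.zeros((n_ind, k, 2))
    ids, sp_labels, ind_shapes = [], [], []
    row = 0
    for s, sp in enumerate(species):
        for i in range(spec.n_per_species):
            ids.append(f"{sp}_i{i + 1:03d}")
            sp_labels.append(sp)
            ind_shapes.append(species_means[s] + ind_eff[row])
            row += 1
    ind_shapes = np.stack(ind_shapes)

    device_bias = {d: rng.normal(0.0, spec.device_bias_sd, size=(k, 2))
                   if spec.device_bias_sd > 0 else np.zeros((k, 2))
                   for d in spec.devices}
    observer_bias = {o: rng.normal(0.0, spec.observer_bias_sd, size=(k, 2))
                     if spec.observer_bias_sd > 0 else np.zeros((k, 2))
                     for o in spec.observers}

    def _noise():
        if spec.session_noise_sd == 0:
            return np.zeros((n_ind, k, 2))
        return rng.normal(0.0, spec.session_noise_sd, size=(n_ind, k, 2))

    datasets: dict[str, LandmarkDataset] = {}
    for device in spec.devices:
        for observer in spec.observers:
            for trial in range(1, spec.n_trials + 1):
                label = AcquisitionLabel(device, False, observer, trial)
                coords = ind_shapes + device_bias[device] + observer_bias[observer] + _noise()
                configs = [LandmarkConfiguration(ids[i], coords[i]) for i in range(n_ind)]
                datasets[label.name] = LandmarkDataset(configs, species=sp_labels, label=label)

    # tilted presentation set: first device, first observer, trial 1
    tilt_label = AcquisitionLabel(spec.devices[0], True, spec.observers[0], 1)
    lo, hi = spec.tilt_range_deg
    mags = rng.uniform(lo, hi, size=(n_ind, 2))
    signs = rng.choice([-1.0, 1.0], size=(n_ind, 2))
    angles = mags * signs
    noise = _noise()
    tilt_configs = []
    for i in range(n_ind):
        config3d = LandmarkConfiguration(ids[i], np.column_stack([ind_shapes[i], z]))
        flat = project_tilted(config3d, angles[i, 0], angles[i, 1])
        coords = flat.xy + device_bias[spec.devices[0]] + observer_bias[spec.observers[0]] \
            + noise[i]
        tilt_configs.append(LandmarkConfiguration(ids[i], coords))
    datasets[tilt_label.name] = LandmarkDataset(tilt_configs, species=sp_labels,
                                                label=tilt_label)

    # unknowns: photographed once (first device) and digitised by the first
    # observer, mirroring a fossil set acquired in a single session
    true_species = rng.choice(species, size=spec.n_unknowns,
                              p=np.asarray(spec.unknown_mixture))
    unk_configs, unk_rows = [], []
    for j, sp in enumerate(true_species):
        s = species.index(sp)
        eff = rng.normal(0.0, spec.individual_sd, size=(k, 2)) \
            if spec.individual_sd > 0 else np.zeros((k, 2))
        noise_u = rng.normal(0.0, spec.session_noise_sd, size=(k, 2)) \
            if spec.session_noise_sd > 0 else np.zeros((k, 2))
        coords = species_means[s] + eff + device_bias[spec.devices[0]] \
            + observer_bias[spec.observers[0]] + noise_u
        uid = f"unk{j + 1:03d}"
        unk_configs.append(LandmarkConfiguration(uid, coords))
        unk_rows.append({"specimen_id": uid, "true_species": sp})
    unknowns = LandmarkDataset(unk_configs)

    return SimulatedStudy(spec=spec, datasets=datasets, unknowns=unknowns,
                          truth=pd.DataFrame(unk_rows), template=template,
                          species_means=species_means)
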