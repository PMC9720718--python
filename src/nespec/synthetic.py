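"""Synthetic conformer ensembles with the statistics the analysis assumes.

Real inputs to this pipeline come from a classical MD engine (geometries) and
a TD-DFT engine (vertical excitations).  This module generates both kinds of
input with the features the analysis is sensitive to:

* torsional populations drawn from a von Mises mixture — multimodal, wrapped,
  with tunable concentration kappa (narrower in solution, where conformational
  mobility is reduced);
* a bright excitation energy coupled to one key dihedral through a periodic
  cosine law, E_k = E_ref - a * (1 - cos(delta_k - delta_0)), so that
  conformers away from the reference torsion delta_0 absorb at lower energy
  and the ensemble average red-shifts relative to the single optimised
  structure — the mechanism the opt-vs-conf comparison is built to expose;
* Gaussian noise on the bright energy, and a fixed template of weak
  higher-lying states so records have realistic state stacks.

Frames are i.i.d. draws, not autocorrelated dynamics: the decimated
configurations entering the spectrum average are treated as uncorrelated
anyway, so temporal correlation would add nothing testable.  The cosine
coupling is phenomenological; it creates the red-shift mechanism, it does not
model any real chromophore's electronic structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .conformers import (
    DEFAULT_DIHEDRALS,
    AngleSeries,
    DihedralSpec,
    Frame,
    SamplingSchedule,
    decimation_indices,
    saved_frame_times,
    wrap_angle,
)
from .errors import GenerationError, NoDataError
from .excitations import ConformerRecord, Ensemble, ExcitedState

__all__ = [
    "TorsionModel",
    "CouplingModel",
    "Scenario",
    "ScenarioResult",
    "gen_angle_series",
    "gen_ensemble",
    "write_fixture_logs",
    "frame_with_torsions",
    "frames_from_angle_series",
    "default_scenario",
    "run_scenario",
]


@dataclass(frozen=True)
class TorsionModel:
    """Von Mises mixture over the circle: (center_deg, kappa, weight) triples."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(c), float(k), float(w)) for c, k, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("need >= 1 mixture component")
        if any(k <= 0 for _, k, _ in comps):
            raise ValueError("kappa must be > 0")
        if any(w <= 0 for _, _, w in comps):
            raise ValueError("weights must be positive")
        total = sum(w for _, _, w in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")


@dataclass(frozen=True)
class CouplingModel:
    """Map from the key dihedral to the bright vertical excitation.

    E_k = reference_energy_ev - sign * coupling_amplitude_ev *
    (1 - cos(delta_k - reference_dihedral_deg)) + N(0, noise_sd_ev); the
    default sign (+1) lowers the energy away from the reference torsion, i.e.
    a red-shift of the ensemble.  ``weak_states`` is a template of
    (energy offset above the bright state in eV, oscillator strength) pairs
    appended to every record.
    """

    reference_energy_ev: float = 2.65
    reference_dihedral_deg: float = -76.0
    coupling_amplitude_ev: float = 0.0
    noise_sd_ev: float = 0.0
    bright_f: float = 0.8012
    f_noise_sd: float = 0.0
    sign: float = 1.0
    weak_states: tuple[tuple[float, float], ...] = (
        (0.45, 0.0201),
        (0.63, 0.0550),
        (0.81, 0.0102),
        (0.97, 0.0323),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_amplitude_ev < 0:
            raise ValueError("coupling_amplitude_ev must be >= 0")
        if self.noise_sd_ev < 0 or self.f_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.reference_energy_ev <= 0:
            raise ValueError("reference_energy_ev must be > 0")

    def bright_energy(self, angle_deg: float) -> float:
        """Noise-free bright-state energy at a given dihedral."""
        d = np.deg2rad(angle_deg - self.reference_dihedral_deg)
        return self.reference_energy_ev - self.sign * self.coupling_amplitude_ev * (
            1.0 - np.cos(d)
        )


def gen_angle_series(
    model: TorsionModel, n_frames: int, seed: int, name: str = "delta"
) -> AngleSeries:
    """Draw ``n_frames`` i.i.d. angles from the mixture, wrapped to (-180, 180]."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.array([c for c, _, _ in model.components])
    kappas = np.array([k for _, k, _ in model.components])
    weights = np.array([w for _, _, w in model.components])
    comp = rng.choice(len(centers), size=n_frames, p=weights / weights.sum())
    draws = rng.vonmises(np.deg2rad(centers[comp]), kappas[comp])
    values = tuple(wrap_angle(v) for v in np.rad2deg(draws))
    return AngleSeries(name, values, tuple(range(n_frames)))


def gen_ensemble(
    angles: AngleSeries,
    coupling: CouplingModel,
    functional_tag: str = "B3LYP",
    phase_tag: str = "gas",
) -> tuple[Ensemble, ConformerRecord]:
    """One conformer record per angle, plus the companion optimised record.

    The opt record carries the bright state at exactly the reference dihedral
    (no noise) with the same weak-state template, so opt-vs-conf shifts are
    attributable purely to the torsional population.  Reproducible per
    ``coupling.seed``; a parameter set driving any energy non-positive raises
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(coupling.seed)
    n = len(angles)
    e_noise = rng.normal(0.0, 1.0, size=n) * coupling.noise_sd_ev
    f_noise = rng.normal(0.0, 1.0, size=n) * coupling.f_noise_sd
    records = []
    for pos, (idx, angle) in enumerate(zip(angles.frame_indices, angles.values)):
        e_bright = coupling.bright_energy(angle) + e_noise[pos]
        f_bright = max(coupling.bright_f + f_noise[pos], 0.0)
        if e_bright <= 0:
            raise GenerationError(
                f"conformer {idx}: bright energy {e_bright:.4f} eV <= 0; reduce "
                "coupling amplitude or noise"
            )
        states = [ExcitedState(1, e_bright, f_bright)]
        for j, (offset, f) in enumerate(coupling.weak_states, start=2):
            states.append(ExcitedState(j, e_bright + offset, f))
        records.append(
            ConformerRecord(int(idx), tuple(states), functional_tag, phase_tag, "synthetic")
        )
    opt_states = [ExcitedState(1, coupling.reference_energy_ev, coupling.bright_f)]
    for j, (offset, f) in enumerate(coupling.weak_states, start=2):
        opt_states.append(ExcitedState(j, coupling.reference_energy_ev + offset, f))
    opt = ConformerRecord("opt", tuple(opt_states), functional_tag, phase_tag, "synthetic")
    return Ensemble(tuple(records)), opt


def write_fixture_logs(ensemble: Ensemble, directory: str | Path) -> list[Path]:
    """Write one Gaussian-dialect log excerpt per conformer.

    Printed precision: 4 decimals (eV), 2 decimals (nm), 4 decimals (f) —
    lossless at that precision when re-parsed.  Returns the written paths.
    """
    if not ensemble.records:
        raise NoDataError("cannot write fixture logs for an empty ensemble")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .constants import HC_EV_NM

    paths = []
    for rec in ensemble.records:
        lines = [
            f" Conformer {rec.conformer_id} ({rec.functional_tag}, {rec.phase_tag})",
            " Excitation energies and oscillator strengths:",
            "",
        ]
        for s in rec.states:
            lam = HC_EV_NM / s.energy_eV
            lines.append(
                f" Excited State   {s.state_index}:      Singlet-A      "
                f"{s.energy_eV:.4f} eV  {lam:.2f} nm  f={s.oscillator_strength:.4f}"
                "  <S**2>=0.000"
            )
            lines.append("       (transition amplitudes omitted)")
        path = directory / f"conf_{rec.conformer_id}.log"
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# toy geometries realising requested torsions


def frame_with_torsions(
    targets: Mapping[str, float],
    specs: Mapping[str, DihedralSpec] | None = None,
    frame_index: int = 0,
    time_ps: float = 0.0,
) -> Frame:
    """A minimal synthetic molecule whose quadruples realise the requested torsions.

    For each named dihedral the central B-C bond and the far C-D bond are laid
    down in a fixed plane and the near atom A is placed by an explicit rotation
    about B-C, so the constructed torsion equals the target exactly (up to
    floating point).  Quadruples sharing their last three atoms (as eta/zeta
    do) reuse the same placed core.  Unrelated quadruples are placed in
    disjoint regions of space.
    """
    specs = dict(specs or DEFAULT_DIHEDRALS)
    atoms: dict[str, np.ndarray] = {}
    offset = np.zeros(3)
    for name, phi in targets.items():
        if name not in specs:
            raise KeyError(f"no dihedral spec named {name!r}")
        if not (-180.0 < phi <= 180.0 or phi == -180.0):
            raise ValueError(f"target {phi} outside (-180, 180]")
        a_lbl, b_lbl, c_lbl, d_lbl = specs[name].atoms
        if all(lbl in atoms for lbl in (b_lbl, c_lbl, d_lbl)):
            b, c, d = atoms[b_lbl], atoms[c_lbl], atoms[d_lbl]
        elif any(lbl in atoms for lbl in (b_lbl, c_lbl, d_lbl)):
            raise GenerationError(
                f"dihedral {name!r} partially overlaps an already placed quadruple"
            )
        else:
            b = offset + np.array([0.0, 0.0, 0.0])
            c = offset + np.array([1.5, 0.0, 0.0])
            d = offset + np.array([1.5, 1.5, 0.0])
            atoms[b_lbl], atoms[c_lbl], atoms[d_lbl] = b, c, d
            offset = offset + np.array([0.0, 0.0, 10.0])
        if a_lbl in atoms:
            raise GenerationError(f"atom {a_lbl!r} already placed by another dihedral")
        # rotate the cis reference position of A about the B->C axis by -phi:
        # with D fixed in the +y half-plane this realises torsion(A,B,C,D) = phi
        rad = np.deg2rad(wrap_angle(phi))
        atoms[a_lbl] = b + 1.5 * np.array([0.0, np.cos(rad), -np.sin(rad)])
    labels = tuple(atoms)
    coords = np.array([atoms[lbl] for lbl in labels])
    return Frame(frame_index, time_ps, labels, coords)


def frames_from_angle_series(
    series_by_name: Mapping[str, AngleSeries],
    times_ps: Sequence[float] | None = None,
    specs: Mapping[str, DihedralSpec] | None = None,
) -> list[Frame]:
    """A toy trajectory realising the given angle series frame by frame."""
    first = next(iter(series_by_name.values()))
    n = len(first)
    if any(len(s) != n for s in series_by_name.values()):
        raise ValueError("all angle series must have equal length")
    frames = []
    for pos in range(n):
        idx = first.frame_indices[pos]
        t = times_ps[pos] if times_ps is not None else float(pos)
        targets = {name: s.values[pos] for name, s in series_by_name.items()}
        frames.append(frame_with_torsions(targets, specs, frame_index=idx, time_ps=t))
    return frames


# ---------------------------------------------------------------------------
# named scenarios


@dataclass(frozen=True)
class Scenario:
    """A fully specified synthetic study condition (one functional, one phase)."""

    name: str
    functional_tag: str
    phase_tag: str
    torsion: TorsionModel
    coupling: CouplingModel
    schedule: SamplingSchedule = SamplingSchedule()


@dataclass(frozen=True)
class ScenarioResult:
    """Everything one scenario run produces."""

    scenario: Scenario
    angles: AngleSeries  # all saved frames
    decimated_angles: AngleSeries  # frames passed to the excitation stage
    ensemble: Ensemble
    opt_record: ConformerRecord
    times_ps: tuple[float, ...]


def default_scenario(phase: str = "gas", functional_tag: str = "B3LYP") -> Scenario:
    """The stock gas / solution study conditions.

    Gas phase: bimodal key torsion at -113 and -76 degrees (kappa = 50, the
    off-minimum mode three times as populated), reference torsion at the -76
    minimum, coupling amplitude 1.2 eV — the ensemble maximum then sits about
    0.2 eV below the static one.  Solution: modes at -115 and -64 degrees
    with kappa = 150 (solvent damps the torsional mobility), reference at
    -64, amplitude 0.35 eV and a lower reference energy (solvatochromic
    red-shift), landing an opt-vs-conf shift of about 0.1 eV.
    """
    if phase == "gas":
        torsion = TorsionModel(((-113.0, 50.0, 0.75), (-76.0, 50.0, 0.25)))
        coupling = CouplingModel(
            reference_energy_ev=2.65,
            reference_dihedral_deg=-76.0,
            coupling_amplitude_ev=1.2,
            noise_sd_ev=0.02,
        )
    elif phase == "solution":
        torsion = TorsionModel(((-115.0, 150.0, 0.75), (-64.0, 150.0, 0.25)))
        coupling = CouplingModel(
            reference_energy_ev=2.30,
            reference_dihedral_deg=-64.0,
            coupling_amplitude_ev=0.35,
            noise_sd_ev=0.02,
        )
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'gas' or 'solution'")
    return Scenario(f"{phase}-default", functional_tag, phase, torsion, coupling)


def run_scenario(scenario: Scenario, seed: int) -> ScenarioResult:
    """Sample the schedule, decimate, and generate the excitation ensemble.

    ``seed`` drives both the torsional draws and the excitation noise through
    independent child seeds, so one integer reproduces the whole run.
    """
    angle_seed, noise_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31)
    )
    times = saved_frame_times(scenario.schedule)
    if not times:
        raise GenerationError("schedule produces no frames")
    angles = gen_angle_series(scenario.torsion, len(times), angle_seed)
    keep = decimation_indices(len(times), scenario.schedule.decimation_stride)
    decimated = angles.subset(keep)
    coupling = replace(scenario.coupling, seed=noise_seed)
    ensemble, opt = gen_ensemble(
        decimated, coupling, scenario.functional_tag, scenario.phase_tag
    )
    return ScenarioResult(scenario, angles, decimated, ensemble, opt, tuple(times))
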