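"""Static-vs-ensemble and gas-vs-solution spectral comparisons.

The headline quantities of the workflow: the red-shift (in eV) between the
absorption maximum computed on a single optimised structure ("opt") and the
one averaged over MD conformers ("conf"), the solvent-induced shift of
lambda_max (in nm), and sub-ensemble spectra restricted to conformers inside
a circular window of a key dihedral — the diagnostic that attributes the
opt/conf shift to a specific internal degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .conformers import AngleSeries, circular_difference
from .constants import HC_EV_NM
from .errors import EmptyWindowError, ValidationError
from .excitations import ConformerRecord, Ensemble
from .spectrum import (
    BroadeningParams,
    Spectrum,
    lambda_max,
    normalize_spectrum,
    reconstruct_spectrum,
)

__all__ = [
    "ShiftReport",
    "DihedralWindow",
    "shift_ev",
    "solvent_shift_nm",
    "windowed_spectrum",
    "build_shift_report",
    "write_shift_reports",
]


@dataclass(frozen=True)
class ShiftReport:
    """One row of the opt-vs-conf comparison for a (functional, phase) pair.

    ``delta_E_eV`` = hc*(1/lambda_opt - 1/lambda_conf): positive when the
    conformational average is red-shifted relative to the optimised structure.
    ``solvent_shift_nm`` is filled in only when both phases are available.
    """

    functional_tag: str
    phase_tag: str
    lambda_conf_nm: float
    lambda_opt_nm: float
    delta_E_eV: float
    solvent_shift_nm: float | None = None


@dataclass(frozen=True)
class DihedralWindow:
    """A circular interval center ± half_width (degrees) on a named dihedral."""

    angle_name: str
    center_deg: float
    half_width_deg: float

    def __post_init__(self) -> None:
        if self.half_width_deg <= 0:
            raise ValueError("half_width_deg must be > 0")

    def contains(self, angle_deg: float) -> bool:
        return abs(circular_difference(angle_deg, self.center_deg)) <= self.half_width_deg


def shift_ev(lambda_opt_nm: float, lambda_conf_nm: float) -> float:
    """Energy shift hc*(1/lambda_opt - 1/lambda_conf) in eV.

    Positive when the conformational average lies at longer wavelength
    (lower energy) than the static spectrum, i.e. a red-shift.
    """
    if lambda_opt_nm <= 0 or lambda_conf_nm <= 0:
        raise ValueError("wavelengths must be positive")
    return HC_EV_NM * (1.0 / lambda_opt_nm - 1.0 / lambda_conf_nm)


def solvent_shift_nm(lambda_solution_nm: float, lambda_gas_nm: float) -> float:
    """Solution-minus-gas lambda_max difference in nm; positive = red-shift."""
    return lambda_solution_nm - lambda_gas_nm


def windowed_spectrum(
    ensemble: Ensemble,
    angle_series: AngleSeries,
    window: DihedralWindow,
    params: BroadeningParams = BroadeningParams(),
) -> Spectrum:
    """Normalised spectrum of the conformers whose dihedral falls in ``window``.

    ``angle_series`` must carry one angle per ensemble conformer, keyed by
    frame index == conformer id.  Raises :class:`EmptyWindowError` (listing
    the nearest populated angles) if no conformer qualifies.
    """
    angle_of = dict(zip(angle_series.frame_indices, angle_series.values))
    selected: list[ConformerRecord] = []
    angles_seen: list[float] = []
    for rec in ensemble.records:
        key = int(rec.conformer_id)
        if key not in angle_of:
            raise ValidationError(
                f"no angle for conformer {rec.conformer_id} in series {angle_series.name!r}"
            )
        angle = angle_of[key]
        angles_seen.append(angle)
        if window.contains(angle):
            selected.append(rec)
    if not selected:
        nearest = sorted(
            angles_seen, key=lambda a: abs(circular_difference(a, window.center_deg))
        )[:5]
        raise EmptyWindowError(
            f"window {window.angle_name} = {window.center_deg} ± "
            f"{window.half_width_deg}° selects no conformers; nearest populated "
            f"angles: {[round(a, 1) for a in nearest]}"
        )
    spec = reconstruct_spectrum(Ensemble(tuple(selected)), params)
    spec.provenance["window"] = (
        window.angle_name,
        window.center_deg,
        window.half_width_deg,
        len(selected),
    )
    return normalize_spectrum(spec)


def build_shift_report(
    conf_ensemble: Ensemble,
    opt_record: ConformerRecord,
    params: BroadeningParams = BroadeningParams(),
) -> ShiftReport:
    """Compute lambda_max for the conformational ensemble and the optimised
    structure and their energy shift; tags must match between the two inputs."""
    if (opt_record.functional_tag, opt_record.phase_tag) != (
        conf_ensemble.functional_tag,
        conf_ensemble.phase_tag,
    ):
        raise ValidationError(
            "opt record and conf ensemble carry different functional/phase tags: "
            f"{(opt_record.functional_tag, opt_record.phase_tag)} vs "
            f"{(conf_ensemble.functional_tag, conf_ensemble.phase_tag)}"
        )
    lam_conf = lambda_max(reconstruct_spectrum(conf_ensemble, params))
    lam_opt = lambda_max(reconstruct_spectrum(opt_record, params))
    return ShiftReport(
        functional_tag=conf_ensemble.functional_tag,
        phase_tag=conf_ensemble.phase_tag,
        lambda_conf_nm=lam_conf,
        lambda_opt_nm=lam_opt,
        delta_E_eV=shift_ev(lam_opt, lam_conf),
    )


def write_shift_reports(
    reports: Iterable[ShiftReport] | ShiftReport, path: str | Path
) -> None:
    """Write shift reports as a delimited table (one row per functional/phase)."""
    if isinstance(reports, ShiftReport):
        reports = [reports]
    rows = [
        {
            "functional": r.functional_tag,
            "phase": r.phase_tag,
            "conf_nm": r.lambda_conf_nm,
            "opt_nm": r.lambda_opt_nm,
            "delta_E_eV": r.delta_E_eV,
            "solvent_shift_nm": r.solvent_shift_nm,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
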