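"""Per-conformer vertical excitation records and their I/O.

Each sampled geometry R_k carries a stack of vertical transitions
(ΔE_IL, f_IL) computed by a TD-DFT engine.  Two exchange formats are
supported: excerpts in the Gaussian-16 log dialect
(``Excited State  N: ... <E> eV <λ> nm  f=<f>``) and a flat CSV table with
one row per (conformer, state).  Parsed energies and wavelengths are
cross-checked against hc = 1239.841984 eV·nm.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .constants import HC_EV_NM
from .errors import NoDataError, ParseError, ValidationError

__all__ = [
    "ExcitedState",
    "ConformerRecord",
    "Ensemble",
    "parse_gaussian_excited_states",
    "read_state_table",
    "write_state_table",
    "bright_state",
    "STATE_TABLE_COLUMNS",
]

#: nm·eV slack allowed between a parsed wavelength and hc/E (log files print
#: both to limited precision).
_HC_SLACK_NM_EV = 0.5

STATE_TABLE_COLUMNS = ["conformer_id", "state_index", "energy_eV", "oscillator_strength"]


@dataclass(frozen=True)
class ExcitedState:
    """One vertical transition: state index L, ΔE_IL in eV, f_IL dimensionless."""

    state_index: int
    energy_eV: float
    oscillator_strength: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.state_index < 1:
            raise ValidationError(f"state_index must be >= 1, got {self.state_index}")
        if self.energy_eV <= 0:
            raise ValidationError(
                f"state {self.state_index}: energy must be positive, got {self.energy_eV}"
            )
        if self.oscillator_strength < 0:
            raise ValidationError(
                f"state {self.state_index}: oscillator strength must be >= 0, "
                f"got {self.oscillator_strength}"
            )
        if self.wavelength_nm is None:
            object.__setattr__(self, "wavelength_nm", HC_EV_NM / self.energy_eV)
        elif abs(self.wavelength_nm * self.energy_eV - HC_EV_NM) > _HC_SLACK_NM_EV:
            raise ValidationError(
                f"state {self.state_index}: energy {self.energy_eV} eV and wavelength "
                f"{self.wavelength_nm} nm are inconsistent with hc = {HC_EV_NM} eV·nm"
            )


@dataclass(frozen=True)
class ConformerRecord:
    """All excited states computed at one sampled geometry R_k."""

    conformer_id: int | str
    states: tuple[ExcitedState, ...]
    functional_tag: str = ""
    phase_tag: str = "gas"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not self.states:
            raise ValidationError(f"conformer {self.conformer_id}: needs >= 1 state")
        indices = [s.state_index for s in self.states]
        if len(set(indices)) != len(indices):
            raise ValidationError(
                f"conformer {self.conformer_id}: duplicate state indices {indices}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Ensemble:
    """The N_p sampled conformers entering the spectrum average.

    Functional and phase tags must be homogeneous; a mixed ensemble would
    average incommensurable excitation energies and is rejected.  State counts
    may differ between records (a conformer occasionally needs extra states to
    cover the visible window); heterogeneity only triggers a warning.
    """

    records: tuple[ConformerRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise NoDataError("an ensemble needs >= 1 conformer record")
        tags = {(r.functional_tag, r.phase_tag) for r in self.records}
        if len(tags) > 1:
            raise ValidationError(f"mixed functional/phase tags in ensemble: {sorted(tags)}")
        n_states = {r.n_states for r in self.records}
        if len(n_states) > 1:
            warnings.warn(
                f"heterogeneous state counts within ensemble: {sorted(n_states)}",
                stacklevel=2,
            )

    @property
    def n_p(self) -> int:
        return len(self.records)

    @property
    def functional_tag(self) -> str:
        return self.records[0].functional_tag

    @property
    def phase_tag(self) -> str:
        return self.records[0].phase_tag


# ---------------------------------------------------------------------------
# Gaussian-log dialect

_STATE_RE = re.compile(
    r"Excited State\s+(\d+):\s+\S+\s+([-+]?\d+\.?\d*)\s*eV\s+([-+]?\d+\.?\d*)\s*nm\s+"
    r"f\s*=\s*([-+]?\d+\.?\d*)"
)


def parse_gaussian_excited_states(
    source: str | Path | io.TextIOBase,
    conformer_id: int | str = 0,
    functional_tag: str = "",
    phase_tag: str = "gas",
) -> ConformerRecord:
    """Parse a Gaussian-16-style log excerpt into a :class:`ConformerRecord`.

    Only lines anchored on the literal tokens ``Excited State`` and ``f=`` are
    consumed; surrounding noise is ignored.  When a state index is printed
    more than once (Gaussian re-prints the state table after density
    refinement), the later block supersedes the earlier one.
    """
    if isinstance(source, Path):
        text, provenance = source.read_text(), str(source)
    elif isinstance(source, str):
        text, provenance = source, "<string>"
    else:
        text, provenance = source.read(), getattr(source, "name", "<stream>")

    states: dict[int, ExcitedState] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if "Excited State" not in line:
            continue
        m = _STATE_RE.search(line)
        if m is None:
            raise ParseError(f"malformed excited-state line {line.strip()!r}", lineno)
        idx = int(m.group(1))
        try:
            energy = float(m.group(2))
            wavelength = float(m.group(3))
            f = float(m.group(4))
        except ValueError:
            raise ParseError(f"unparsable numeric field in {line.strip()!r}", lineno) from None
        states[idx] = ExcitedState(idx, energy, f, wavelength)
    if not states:
        raise NoDataError(f"no excited states found in {provenance}")
    ordered = tuple(states[i] for i in sorted(states))
    return ConformerRecord(conformer_id, ordered, functional_tag, phase_tag, provenance)


# ---------------------------------------------------------------------------
# state tables


def read_state_table(
    path: str | Path, functional_tag: str = "", phase_tag: str = "gas"
) -> Ensemble:
    """Read a CSV state table into an :class:`Ensemble`.

    The header must contain ``conformer_id,state_index,energy_eV,
    oscillator_strength``.  Rows are grouped by conformer in first-appearance
    order; within a conformer, states are ordered by state index, so row
    order never changes the resulting ensemble.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"state table {path} missing columns {missing}")
    records = []
    for cid in pd.unique(df["conformer_id"]):
        sub = df[df["conformer_id"] == cid].sort_values("state_index")
        states = []
        for row in sub.itertuples():
            rownum = int(row.Index) + 2  # header is line 1
            try:
                states.append(
                    ExcitedState(
                        int(row.state_index),
                        float(row.energy_eV),
                        float(row.oscillator_strength),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
        cid_native = cid.item() if hasattr(cid, "item") else cid
        records.append(
            ConformerRecord(cid_native, tuple(states), functional_tag, phase_tag, str(path))
        )
    return Ensemble(tuple(records))


def write_state_table(ensemble: Ensemble | Iterable[ConformerRecord], path: str | Path) -> None:
    """Write an ensemble (or records) as the CSV exactly inverse to
    :func:`read_state_table`; floats round-trip at full precision."""
    records: Sequence[ConformerRecord]
    records = ensemble.records if isinstance(ensemble, Ensemble) else tuple(ensemble)
    rows = [
        (r.conformer_id, s.state_index, s.energy_eV, s.oscillator_strength)
        for r in records
        for s in r.states
    ]
    # %.17g is the shortest format guaranteed to round-trip float64 exactly
    pd.DataFrame(rows, columns=STATE_TABLE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def bright_state(record: ConformerRecord) -> ExcitedState:
    """The state with maximal oscillator strength; ties go to the lowest index.

    A single bright transition dominating the visible band is the regime this
    pipeline targets.
    """
    return max(record.states, key=lambda s: (s.oscillator_strength, -s.state_index))
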