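"""Synthetic assay datasets, curve file I/O, and experiment designs.

The generators produce counts-per-minute concentration-response curves from
the cooperative isotherms through the linear signal model
``CPM = Bmax * f + ns * [L] + baseline`` with optional seeded Gaussian noise
(absolute or proportional).  Noisy CPM values are kept as generated — never
clipped at zero — so downstream fits stay unbiased at low signal.

Curves are serialized as delimited text (comma or tab, sniffed from the
header): saturation files have columns ``ligand_conc_M, cpm``; competition
files ``inhibitor_conc_M, cpm`` plus a ``# radioligand_conc_M:`` header
comment.  Concentrations are written in scientific notation with 12
significant digits so a write/read round-trip is lossless for practical
purposes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fitting import BindingCurve, SignalModel
from .isotherms import (
    CompetitionParams,
    SaturationParams,
    competition_fraction,
    saturation_fraction,
)

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "generate_saturation_dataset",
    "generate_competition_dataset",
    "read_curve",
    "write_curve",
]


@dataclass(frozen=True)
class NoiseModel:
    """Seeded Gaussian noise, absolute (CPM) or proportional (fraction of signal)."""

    kind: str = "gaussian_proportional"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_absolute", "gaussian_proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not (self.scale >= 0):
            raise ValueError(f"scale must be non-negative, got {self.scale}")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        if self.scale == 0:
            return signal.copy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "gaussian_absolute":
            sd = np.full_like(signal, self.scale)
        else:
            sd = self.scale * np.abs(signal)
        return signal + rng.normal(0.0, 1.0, size=signal.shape) * sd


@dataclass(frozen=True)
class ExperimentDesign:
    """Concentration grid of an assay: range, point count, spacing."""

    conc_min: float
    conc_max: float
    n_points: int = 12
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not (0 < self.conc_min < self.conc_max):
            raise ValueError("need 0 < conc_min < conc_max")
        if not (isinstance(self.n_points, (int, np.integer)) and self.n_points >= 2):
            raise ValueError("n_points must be an integer >= 2")
        if self.spacing not in ("log", "linear"):
            raise ValueError(f"spacing must be 'log' or 'linear', got {self.spacing!r}")

    def grid(self) -> np.ndarray:
        if self.spacing == "log":
            return np.logspace(np.log10(self.conc_min), np.log10(self.conc_max),
                               self.n_points)
        return np.linspace(self.conc_min, self.conc_max, self.n_points)


def generate_saturation_dataset(
    params: SaturationParams,
    signal: SignalModel,
    design: ExperimentDesign,
    noise: NoiseModel = NoiseModel(),
    label: str = "",
) -> BindingCurve:
    """Synthetic saturation curve: cooperative isotherm through the signal model."""
    conc = design.grid()
    f = saturation_fraction(conc / params.kd, params.alpha_l)
    cpm = signal.bmax * f + signal.ns_slope * conc + signal.baseline
    return BindingCurve("saturation", conc, noise.apply(np.asarray(cpm)), label=label)


def generate_competition_dataset(
    params: CompetitionParams,
    radioligand_conc: float,
    signal: SignalModel,
    design: ExperimentDesign,
    noise: NoiseModel = NoiseModel(),
    label: str = "",
) -> BindingCurve:
    """Synthetic competition curve; the midpoint follows
    ``IC50 = EC50_I [L] / EC50_L`` and the shape is set by beta."""
    if not (radioligand_conc > 0):
        raise ValueError("radioligand_conc must be positive")
    conc = design.grid()
    ic50 = params.ic50(radioligand_conc)
    f = competition_fraction(conc / ic50, params.beta)
    cpm = signal.bmax * f + signal.baseline
    return BindingCurve(
        "competition", conc, noise.apply(np.asarray(cpm)),
        radioligand_conc=radioligand_conc, label=label,
    )


_COLUMNS = {"saturation": "ligand_conc_M", "competition": "inhibitor_conc_M"}


def write_curve(curve: BindingCurve, path, delimiter: str = ",") -> None:
    """Serialize a curve as delimited text with a header row."""
    if delimiter not in (",", "\t"):
        raise ValueError("delimiter must be ',' or tab")
    buf = io.StringIO()
    if curve.label:
        buf.write(f"# label: {curve.label}\n")
    if curve.assay_type == "competition":
        buf.write(f"# radioligand_conc_M: {curve.radioligand_conc:.12e}\n")
    buf.write(f"{_COLUMNS[curve.assay_type]}{delimiter}cpm\n")
    for c, s in zip(curve.concentrations, curve.signal):
        buf.write(f"{c:.12e}{delimiter}{s:.12f}\n")
    Path(path).write_text(buf.getvalue())


def read_curve(path, radioligand_conc: float | None = None) -> BindingCurve:
    """Parse a curve file, sniffing the delimiter from the header row.

    Malformed rows (wrong column count, non-numeric cells, negative
    concentrations) are rejected with their line number.
    """
    text = Path(path).read_text()
    label = ""
    file_radioligand: float | None = None
    header: str | None = None
    header_lineno = 0
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("label:"):
                label = body.split(":", 1)[1].strip()
            elif body.lower().startswith("radioligand_conc_m:"):
                try:
                    file_radioligand = float(body.split(":", 1)[1])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: bad radioligand concentration") from exc
            continue
        if header is None:
            header, header_lineno = stripped, lineno
        else:
            rows.append((lineno, stripped))
    if header is None:
        raise ValueError("file has no header row")

    delimiter = "\t" if "\t" in header else ","
    cols = [c.strip() for c in header.split(delimiter)]
    assay_type = None
    for atype, cname in _COLUMNS.items():
        if cols[:1] == [cname]:
            assay_type = atype
    if assay_type is None or len(cols) < 2 or cols[1] != "cpm":
        raise ValueError(
            f"line {header_lineno}: expected header '<ligand_conc_M|inhibitor_conc_M>"
            f"{delimiter}cpm', got {header!r}"
        )

    conc, sig = [], []
    for lineno, row in rows:
        cells = [c.strip() for c in row.split(delimiter)]
        if len(cells) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(cells)}")
        try:
            c, s = float(cells[0]), float(cells[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric cell in {row!r}") from exc
        if c < 0:
            raise ValueError(f"line {lineno}: negative concentration {c}")
        conc.append(c)
        sig.append(s)

    rc = radioligand_conc if radioligand_conc is not None else file_radioligand
    return BindingCurve(
        assay_type, np.array(conc), np.array(sig),
        radioligand_conc=rc if assay_type == "competition" else None,
        label=label,
    )
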