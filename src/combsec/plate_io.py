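"""Plate-level data model and CSV I/O for multiplexed protein-release screens.

A screen cultivates disease-associated (``D``) and healthy (``H``) samples on
one microtiter plate, exposes the ``D`` samples to every treatment from an
exhaustive combination panel, optionally stimulates all samples with protein
mixtures, and measures the release of ``d`` proteins per well (values
proportional to concentration, e.g. multiplex immunoassay fluorescence).
Cell-free ``BLANK`` wells measure the assay background.

The plate CSV dialect is self-describing: the first row is a header with the
annotation columns ``well``, ``tissue``, ``treatment``, ``stimulation``,
``replicate`` followed by one column per protein.  Treatments are encoded as
drug indices joined without separator (``"12"`` = drugs {1, 2}; ``"-"`` or
empty = untreated); stimulations as ``"S1"``..``"Sk"`` with ``"-"`` for
unstimulated.  Any column order is accepted via a schema mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import PlateFormatError

__all__ = [
    "TISSUE_D",
    "TISSUE_H",
    "TISSUE_BLANK",
    "TreatmentCode",
    "CellState",
    "WellRecord",
    "PlateTable",
    "PlateSchema",
    "read_plate_csv",
    "write_plate_csv",
    "summarize_layout",
    "write_results",
]

TISSUE_D = "D"
TISSUE_H = "H"
TISSUE_BLANK = "BLANK"
_VALID_TISSUES = frozenset({TISSUE_D, TISSUE_H, TISSUE_BLANK})

_UNTREATED_TOKENS = frozenset({"", "-", "TO", "T0", "NONE"})
_UNSTIMULATED_TOKENS = frozenset({"", "-", "S0", "SO", "0", "NONE"})


class TreatmentCode:
    """An order-free subset of the single-drug panel.

    The empty set denotes the untreated state (``To``).  Labels render the
    drug indices sorted ascending (``T13``, never ``T31``), so
    ``TreatmentCode([1, 2]) == TreatmentCode([2, 1])`` and both render
    ``"T12"``.
    """

    __slots__ = ("drugs",)

    def __init__(self, drugs: Iterable[int] = ()):
        ds = frozenset(int(i) for i in drugs)
        if any(i < 1 for i in ds):
            raise ValueError(f"drug indices must be >= 1, got {sorted(ds)}")
        object.__setattr__(self, "drugs", ds)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("TreatmentCode is immutable")

    @classmethod
    def untreated(cls) -> "TreatmentCode":
        return cls(())

    @classmethod
    def parse(cls, text: str) -> "TreatmentCode":
        """Parse ``"12"``, ``"T12"``, ``"1+2"``, ``"1,2"``, ``"-"`` or ``""``."""
        s = str(text).strip().upper()
        if s in _UNTREATED_TOKENS:
            return cls(())
        if s.startswith("T"):
            s = s[1:]
        if s in _UNTREATED_TOKENS:
            return cls(())
        for sep in ("+", ",", ";", " "):
            if sep in s:
                parts = [p for p in s.split(sep) if p]
                try:
                    return cls(int(p) for p in parts)
                except ValueError:
                    raise PlateFormatError(f"unparseable treatment code {text!r}")
        if not s.isdigit():
            raise PlateFormatError(f"unparseable treatment code {text!r}")
        # single digits per drug index (panels of up to 9 drugs)
        return cls(int(ch) for ch in s)

    @property
    def is_untreated(self) -> bool:
        return not self.drugs

    @property
    def order(self) -> int:
        """Number of single drugs in the (combination) treatment."""
        return len(self.drugs)

    @property
    def label(self) -> str:
        if not self.drugs:
            return "To"
        return "T" + "".join(str(i) for i in sorted(self.drugs))

    def issubset(self, other: "TreatmentCode") -> bool:
        return self.drugs <= other.drugs

    def is_proper_subset(self, other: "TreatmentCode") -> bool:
        return self.drugs < other.drugs

    def __eq__(self, other) -> bool:
        return isinstance(other, TreatmentCode) and self.drugs == other.drugs

    def __hash__(self) -> int:
        return hash(("TreatmentCode", self.drugs))

    def __lt__(self, other: "TreatmentCode") -> bool:
        # deterministic panel order: by order, then lexicographic on indices
        if not isinstance(other, TreatmentCode):
            return NotImplemented
        return (len(self.drugs), tuple(sorted(self.drugs))) < (
            len(other.drugs),
            tuple(sorted(other.drugs)),
        )

    def __le__(self, other: "TreatmentCode") -> bool:
        return self == other or self < other

    def __repr__(self) -> str:
        return f"TreatmentCode({sorted(self.drugs)})"

    def __str__(self) -> str:
        return self.label


def parse_stimulation(text: str | int) -> int:
    """Parse ``"S2"``, ``"2"`` or ``"-"`` into a stimulation index (0 = none)."""
    if isinstance(text, (int, np.integer)):
        idx = int(text)
    else:
        s = str(text).strip().upper()
        if s in _UNSTIMULATED_TOKENS:
            return 0
        if s.startswith("S"):
            s = s[1:]
        if not s.isdigit():
            raise PlateFormatError(f"unparseable stimulation code {text!r}")
        idx = int(s)
    if idx < 0:
        raise PlateFormatError(f"stimulation index must be >= 0, got {idx}")
    return idx


def stimulation_label(stimulation: int) -> str:
    return "So" if stimulation == 0 else f"S{stimulation}"


class CellState(NamedTuple):
    """One (tissue, treatment, stimulation) condition on a plate."""

    tissue: str
    treatment: TreatmentCode
    stimulation: int

    @property
    def label(self) -> str:
        return f"({self.tissue}, {self.treatment.label}, {stimulation_label(self.stimulation)})"


@dataclass(eq=False)
class WellRecord:
    """One well: annotations plus its raw measurement vector ``f``."""

    well_id: str
    tissue: str
    treatment: TreatmentCode
    stimulation: int
    replicate: int
    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1:
            raise PlateFormatError(f"well {self.well_id}: f must be a 1-D vector")
        if not np.all(np.isfinite(self.f)):
            raise PlateFormatError(f"well {self.well_id}: non-finite measurement")
        if np.any(self.f < 0):
            raise PlateFormatError(f"well {self.well_id}: negative measurement")
        if self.tissue not in _VALID_TISSUES:
            raise PlateFormatError(
                f"well {self.well_id}: unknown tissue label {self.tissue!r} "
                f"(expected one of {sorted(_VALID_TISSUES)})"
            )
        if self.replicate < 1:
            raise PlateFormatError(
                f"well {self.well_id}: replicate index must be >= 1, got {self.replicate}"
            )
        if self.tissue == TISSUE_BLANK:
            if not self.treatment.is_untreated or self.stimulation != 0:
                raise PlateFormatError(
                    f"well {self.well_id}: BLANK wells must be untreated and unstimulated"
                )
        if self.tissue == TISSUE_H and not self.treatment.is_untreated:
            raise PlateFormatError(
                f"well {self.well_id}: healthy wells are analyzed untreated only"
            )

    @property
    def state(self) -> CellState:
        return CellState(self.tissue, self.treatment, self.stimulation)


@dataclass
class PlateTable:
    """A validated plate: ``N`` wells sharing an ordered protein panel of size ``d``."""

    plate_id: str
    proteins: tuple[str, ...]
    wells: list[WellRecord]
    n_drugs: int = 0

    def __post_init__(self):
        self.proteins = tuple(str(p) for p in self.proteins)
        if len(set(self.proteins)) != len(self.proteins):
            raise PlateFormatError("duplicate protein column names")
        d = len(self.proteins)
        for w in self.wells:
            if w.f.shape[0] != d:
                raise PlateFormatError(
                    f"well {w.well_id}: {w.f.shape[0]} measurements for {d} proteins"
                )
        max_drug = max((max(w.treatment.drugs, default=0) for w in self.wells), default=0)
        if self.n_drugs == 0:
            self.n_drugs = max_drug
        elif max_drug > self.n_drugs:
            raise PlateFormatError(
                f"treatment references drug {max_drug} but n_drugs={self.n_drugs}"
            )

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def d(self) -> int:
        return len(self.proteins)

    def states(self, include_blanks: bool = True) -> dict[CellState, list[WellRecord]]:
        """Group wells by cell state, preserving row order within a state."""
        out: dict[CellState, list[WellRecord]] = {}
        for w in self.wells:
            if not include_blanks and w.tissue == TISSUE_BLANK:
                continue
            out.setdefault(w.state, []).append(w)
        return out

    def blank_wells(self) -> list[WellRecord]:
        return [w for w in self.wells if w.tissue == TISSUE_BLANK]

    def with_wells(self, wells: Sequence[WellRecord]) -> "PlateTable":
        return PlateTable(self.plate_id, self.proteins, list(wells), self.n_drugs)

    def with_proteins(self, keep: Sequence[str]) -> "PlateTable":
        """Restrict the plate to a protein subset (order preserved)."""
        keep_set = set(keep)
        idx = [i for i, p in enumerate(self.proteins) if p in keep_set]
        proteins = tuple(self.proteins[i] for i in idx)
        wells = [
            WellRecord(w.well_id, w.tissue, w.treatment, w.stimulation, w.replicate, w.f[idx])
            for w in self.wells
        ]
        return PlateTable(self.plate_id, proteins, wells, self.n_drugs)

    def matrix(self) -> np.ndarray:
        """The raw N x d measurement matrix in row order."""
        return np.vstack([w.f for w in self.wells]) if self.wells else np.empty((0, self.d))

    def __iter__(self) -> Iterator[WellRecord]:
        return iter(self.wells)


@dataclass(frozen=True)
class PlateSchema:
    """Maps CSV column names onto the plate annotations.

    ``proteins=None`` means: every column not named as an annotation is a
    protein column, in file order.
    """

    well: str = "well"
    tissue: str = "tissue"
    treatment: str = "treatment"
    stimulation: str = "stimulation"
    replicate: str = "replicate"
    proteins: tuple[str, ...] | None = None

    @property
    def annotation_columns(self) -> tuple[str, ...]:
        return (self.well, self.tissue, self.treatment, self.stimulation, self.replicate)


def _parse_tissue(raw: str, row: int) -> str:
    s = str(raw).strip().upper()
    if s in ("D", "DISEASED", "DISEASE"):
        return TISSUE_D
    if s in ("H", "HEALTHY"):
        return TISSUE_H
    if s in ("BLANK", "B", "BG", "BACKGROUND"):
        return TISSUE_BLANK
    raise PlateFormatError(f"row {row}: unknown tissue label {raw!r}")


def read_plate_csv(
    path: str | Path,
    schema: PlateSchema | None = None,
    plate_id: str | None = None,
) -> PlateTable:
    """Read and validate a plate CSV into a :class:`PlateTable`.

    Row order is preserved; measurement strings are parsed as decimal numbers
    (``"."`` separator, no locale sniffing).  Errors carry row/column context.
    """
    path = Path(path)
    schema = schema or PlateSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise PlateFormatError(f"{path.name}: empty plate (no data rows)")

    cols = list(df.columns)
    for name in schema.annotation_columns:
        n = cols.count(name)
        if n == 0:
            raise PlateFormatError(f"{path.name}: missing annotation column {name!r}")
        if n > 1:
            raise PlateFormatError(f"{path.name}: duplicate annotation column {name!r}")
    if schema.proteins is None:
        proteins = tuple(c for c in cols if c not in schema.annotation_columns)
    else:
        proteins = tuple(schema.proteins)
        for p in proteins:
            if p not in cols:
                raise PlateFormatError(f"{path.name}: missing protein column {p!r}")
    if not proteins:
        raise PlateFormatError(f"{path.name}: no protein columns found")

    wells: list[WellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = dict(zip(df.columns, row))
        try:
            replicate = int(str(rec[schema.replicate]).strip())
        except ValueError:
            raise PlateFormatError(
                f"row {i}: non-integer replicate {rec[schema.replicate]!r}"
            )
        values = np.empty(len(proteins))
        for j, p in enumerate(proteins):
            cell = str(rec[p]).strip()
            try:
                values[j] = float(cell)
            except ValueError:
                raise PlateFormatError(
                    f"row {i}, column {p!r}: non-numeric measurement {cell!r}"
                )
        wells.append(
            WellRecord(
                well_id=str(rec[schema.well]).strip(),
                tissue=_parse_tissue(rec[schema.tissue], i),
                treatment=TreatmentCode.parse(rec[schema.treatment]),
                stimulation=parse_stimulation(rec[schema.stimulation]),
                replicate=replicate,
                f=values,
            )
        )
    return PlateTable(plate_id or path.stem, proteins, wells)


def write_plate_csv(plate: PlateTable, path: str | Path) -> Path:
    """Write a plate back to the CSV dialect (round-trips with read_plate_csv)."""
    path = Path(path)
    rows = []
    for w in plate.wells:
        row = {
            "well": w.well_id,
            "tissue": w.tissue,
            "treatment": "-" if w.treatment.is_untreated else "".join(
                str(i) for i in sorted(w.treatment.drugs)
            ),
            "stimulation": "-" if w.stimulation == 0 else f"S{w.stimulation}",
            "replicate": w.replicate,
        }
        row.update({p: np.format_float_positional(v, trim="-") for p, v in zip(plate.proteins, w.f)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def summarize_layout(plate: PlateTable) -> pd.DataFrame:
    """Count wells per (tissue, treatment, stimulation) state.

    The ``wells`` column sums to ``N``; grouping mirrors the plate's
    experimental design table (tissue x treatment x stimulation x replicates).
    """
    rows = []
    for state, ws in plate.states().items():
        rows.append(
            {
                "tissue": state.tissue,
                "treatment": state.treatment.label,
                "stimulation": stimulation_label(state.stimulation),
                "replicates": len(ws),
                "wells": len(ws),
            }
        )
    df = pd.DataFrame(rows, columns=["tissue", "treatment", "stimulation", "replicates", "wells"])
    return df.sort_values(["tissue", "stimulation", "treatment"], ignore_index=True)


def write_results(
    outdir: str | Path,
    artifacts: Mapping[str, object],
    metadata: Mapping[str, object] | None = None,
) -> dict:
    """Persist a result bundle with deterministic file names.

    DataFrames become ``<name>.csv``, matplotlib figures ``<name>.png``,
    JSON-serializable objects ``<name>.json``.  A ``run_metadata.json``
    capturing config + seed is always written.  Returns the manifest.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise PlateFormatError(f"unwritable output directory {outdir}: {exc}")

    manifest: dict = {"files": [], "metadata": dict(metadata or {})}
    for name in sorted(artifacts):
        obj = artifacts[name]
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(outdir / fname, index=False)
        elif hasattr(obj, "savefig"):  # matplotlib Figure
            fname = f"{name}.png"
            obj.savefig(outdir / fname, dpi=150, bbox_inches="tight")
            import matplotlib.pyplot as plt

            plt.close(obj)
        else:
            fname = f"{name}.json"
            with open(outdir / fname, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        manifest["files"].append(fname)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["files"].append("run_metadata.json")
    return manifest
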