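"""Abundance tables, taxonomic aggregation and equilibrium estimation.

Longitudinal 16S-style data enter as a taxa × samples table (counts or
proportions; first column a Greengenes-style lineage such as
``k__Bacteria;p__Firmicutes;...``) plus per-sample metadata (subject,
week of age, treatment group). The pipeline aggregates to a taxonomic
rank (phylum by default), converts to relative abundances with a small
detection floor so every taxon stays strictly positive, and estimates
the equilibrium ``ȳ`` as the mean composition over a chosen week
window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .glv import Trajectory

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "EquilibriumState",
    "read_table",
    "write_table",
    "read_metadata",
    "aggregate_taxa",
    "relative_abundance",
    "estimate_equilibrium",
    "subject_trajectories",
    "DEFAULT_FLOOR",
]

#: Default detection pseudo-proportion replacing zeros.
DEFAULT_FLOOR = 1e-4

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

RELATIVE_SUM_TOL = 1e-8


@dataclass(frozen=True)
class AbundanceTable:
    """Taxa × samples nonnegative matrix with lineage strings."""

    taxa: tuple[str, ...]  # taxon ids (row labels)
    lineages: tuple[str, ...]  # Greengenes-style lineage per taxon
    samples: tuple[str, ...]
    values: np.ndarray  # (n_taxa, n_samples), nonnegative
    is_relative: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if list(self.taxa).count(t) > 1})
            raise ValueError(f"duplicate taxon ids: {dup}")
        if len(set(self.samples)) != len(self.samples):
            dup = sorted({s for s in self.samples if list(self.samples).count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        if values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.taxa)}, {len(self.samples)})"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at taxon {self.taxa[i]!r}, sample "
                f"{self.samples[j]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > RELATIVE_SUM_TOL):
                j = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"relative table column {self.samples[j]!r} sums to "
                    f"{sums[j]:.12g}, expected 1"
                )
        object.__setattr__(self, "values", values)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.lineages),
                            columns=list(self.samples))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: subject id, week of age, group label."""

    frame: pd.DataFrame  # index = sample id; columns subject, week, group

    def __post_init__(self):
        required = {"subject", "week", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dup}")

    def validate_against(self, table: AbundanceTable) -> None:
        missing = [s for s in table.samples if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class EquilibriumState:
    """Data-determined equilibrium ȳ with detection-floor bookkeeping."""

    taxa: tuple[str, ...]
    y_bar: np.ndarray
    window: tuple[float, float]
    floor: float

    def __post_init__(self):
        y = np.asarray(self.y_bar, dtype=float).reshape(-1)
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if np.any(y < self.floor):
            raise ValueError("y_bar components must be >= floor")
        object.__setattr__(self, "y_bar", y)

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxa": list(self.taxa),
                "y_bar": self.y_bar.tolist(),
                "window": list(self.window),
                "floor": self.floor,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read an abundance table (TSV, or read-only BIOM v1 JSON).

    TSV layout: first column the taxon lineage, remaining columns one
    numeric column per sample. Counts vs proportions are detected from
    the column sums.
    """
    path = Path(path)
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    rows = [line.rstrip("\n").split("\t") for line in
            path.read_text().splitlines() if line.strip()]
    header = rows[0]
    samples = tuple(header[1:])
    width = len(header)
    lineages, data = [], []
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path.name}: ragged row {k} ({len(row)} fields, "
                f"expected {width})"
            )
        lineages.append(row[0])
        vals = []
        for j, cell in enumerate(row[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path.name}: malformed numeric cell at row {k}, "
                    f"column {samples[j]!r}: {cell!r}"
                ) from None
        data.append(vals)
    values = np.asarray(data, dtype=float)
    if np.any(values < 0):
        i = int(np.argwhere(values < 0)[0][0])
        raise ValueError(f"{path.name}: negative value in row {lineages[i]!r}")
    sums = values.sum(axis=0)
    is_relative = bool(values.size and np.all(np.abs(sums - 1.0) < 1e-6))
    return AbundanceTable(
        taxa=tuple(lineages),
        lineages=tuple(lineages),
        samples=samples,
        values=values,
        is_relative=is_relative,
    )


def _read_biom_json(path: Path) -> AbundanceTable:
    """Minimal read-only reader for BIOM v1 (JSON) tables."""
    doc = json.loads(path.read_text())
    taxa_ids, lineages = [], []
    for row in doc["rows"]:
        taxa_ids.append(row["id"])
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        lineages.append(";".join(tax) if isinstance(tax, list)
                        else (tax or row["id"]))
    samples = tuple(col["id"] for col in doc["columns"])
    shape = tuple(doc["shape"])
    values = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = v
    else:
        values[:] = np.asarray(doc["data"], dtype=float)
    sums = values.sum(axis=0)
    is_relative = bool(np.all(np.abs(sums - 1.0) < 1e-6))
    return AbundanceTable(
        taxa=tuple(taxa_ids), lineages=tuple(lineages), samples=samples,
        values=values, is_relative=is_relative,
    )


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the TSV layout ``read_table`` reads (lineage first column)."""
    lines = ["taxonomy\t" + "\t".join(table.samples)]
    for lineage, row in zip(table.lineages, table.values):
        lines.append(lineage + "\t" + "\t".join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["week"] = pd.to_numeric(df["week"])
    return SampleMetadata(frame=df)


# ---------------------------------------------------------------------------
# Aggregation and normalisation
# ---------------------------------------------------------------------------

def _rank_label(lineage: str, prefix: str) -> str | None:
    tokens = [t.strip() for t in lineage.split(";")]
    has_any_prefix = any(
        t[:3] in RANK_PREFIXES.values() for t in tokens if len(t) >= 3
    )
    if not has_any_prefix:
        # plain-name fallback: a bare label is taken as the requested rank
        return lineage.strip() or None
    for t in tokens:
        if t.startswith(prefix):
            label = t[len(prefix):].strip()
            return label or None
    return None


def aggregate_taxa(table: AbundanceTable, level: str = "phylum") -> AbundanceTable:
    """Sum rows sharing the same label at a taxonomic rank.

    Lineages lacking the rank are pooled into ``"unclassified"``. Column
    sums are conserved exactly.
    """
    try:
        prefix = RANK_PREFIXES[level.lower()]
    except KeyError:
        raise ValueError(
            f"unknown rank {level!r}; expected one of {sorted(RANK_PREFIXES)}"
        ) from None
    labels = [_rank_label(lin, prefix) for lin in table.lineages]
    if all(lbl is None for lbl in labels):
        raise ValueError(f"no lineage in the table carries the rank {level!r}")
    labels = [lbl if lbl is not None else "unclassified" for lbl in labels]

    order: list[str] = []
    for lbl in labels:
        if lbl not in order:
            order.append(lbl)
    values = np.zeros((len(order), len(table.samples)))
    for lbl, row in zip(labels, table.values):
        values[order.index(lbl)] += row
    return AbundanceTable(
        taxa=tuple(order),
        lineages=tuple(f"{prefix}{lbl}" for lbl in order),
        samples=table.samples,
        values=values,
        is_relative=table.is_relative,
    )


def relative_abundance(
    table: AbundanceTable, floor: float = DEFAULT_FLOOR
) -> AbundanceTable:
    """Convert columns to proportions, replacing zeros by a detection floor.

    Each column is divided by its sum, zeros are set to ``floor`` and the
    column renormalised, so the result is strictly positive and sums to 1.
    """
    values = table.values.copy()
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        total = col.sum()
        if total == 0:
            if floor <= 0:
                raise ValueError(
                    f"all-zero sample {table.samples[j]!r} with floor = 0"
                )
            col = np.full_like(col, floor)
        else:
            col = col / total
            if floor > 0:
                col = np.where(col == 0, floor, col)
        out[:, j] = col / col.sum()
    return AbundanceTable(
        taxa=table.taxa,
        lineages=table.lineages,
        samples=table.samples,
        values=out,
        is_relative=True,
    )


# ---------------------------------------------------------------------------
# Equilibrium estimation
# ---------------------------------------------------------------------------

def estimate_equilibrium(
    table: AbundanceTable,
    meta: SampleMetadata,
    group: str,
    window: tuple[float, float],
    floor: float = DEFAULT_FLOOR,
) -> EquilibriumState:
    """Equilibrium ȳ = mean composition of a group over a week window.

    Averages the relative abundances of every (subject, week) sample of
    the group whose week lies in ``[window[0], window[1]]``; the result
    is clipped below at the detection floor so ȳ stays interior.
    """
    if not table.is_relative:
        raise ValueError("estimate_equilibrium requires a relative table")
    meta.validate_against(table)
    sel = []
    for j, s in enumerate(table.samples):
        row = meta.frame.loc[s]
        if row["group"] == group and window[0] <= float(row["week"]) <= window[1]:
            sel.append(j)
    if len(sel) < 2:
        raise ValueError(
            f"need >= 2 samples of group {group!r} in weeks "
            f"[{window[0]}, {window[1]}]; found {len(sel)}"
        )
    y_bar = table.values[:, sel].mean(axis=1)
    y_bar = np.maximum(y_bar, floor)
    return EquilibriumState(
        taxa=table.taxa, y_bar=y_bar, window=(float(window[0]), float(window[1])),
        floor=floor,
    )


def subject_trajectories(
    table: AbundanceTable,
    meta: SampleMetadata,
    group: str,
    window: tuple[float, float] | None = None,
) -> list[Trajectory]:
    """Per-subject weekly trajectories of a group (for collocation fitting)."""
    if not table.is_relative:
        raise ValueError("subject_trajectories requires a relative table")
    meta.validate_against(table)
    per_subject: dict[str, list[tuple[float, int]]] = {}
    for j, s in enumerate(table.samples):
        row = meta.frame.loc[s]
        if row["group"] != group:
            continue
        week = float(row["week"])
        if window is not None and not (window[0] <= week <= window[1]):
            continue
        per_subject.setdefault(str(row["subject"]), []).append((week, j))
    trajectories = []
    for subject in sorted(per_subject):
        pts = sorted(per_subject[subject])
        times = np.array([w for w, _ in pts])
        states = table.values[:, [j for _, j in pts]].T
        trajectories.append(
            Trajectory(times=times, states=states, taxa=table.taxa)
        )
    return trajectories
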