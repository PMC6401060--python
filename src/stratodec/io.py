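"""File formats and reports: Newick trees, range tables, geography configs.

Two range-table dialects are read and written:

* ``tabular`` -- a TSV with header ``taxon <area> <area> ...`` and one 0/1
  cell per area;
* ``lagrange`` -- the classic distribution-file dialect: a header line
  ``"<ntaxa> <nareas>"`` followed by ``"<taxon> 01010"`` rows.

Readers validate rather than coerce: unknown area labels, duplicate taxa,
all-zero rows, non-ultrametric trees and polytomies are each rejected with
a distinct message.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geography import (
    ALWAYS,
    Area,
    Corridor,
    Geography,
    GeographyError,
    PaleoEvent,
)
from .phylo import Phylogeny, TreeError

__all__ = [
    "TipRangeTable",
    "read_tree",
    "write_tree",
    "read_ranges",
    "write_ranges",
    "load_geography",
    "dump_geography",
    "config_digest",
]


class RangeTableError(ValueError):
    """Malformed range-table input."""


@dataclass
class TipRangeTable:
    """Taxon -> range bitmask over a fixed, ordered area-label list."""

    area_labels: list[str]
    masks: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.area_labels)
        for taxon, mask in self.masks.items():
            if mask == 0:
                raise RangeTableError(f"taxon {taxon!r} occupies no area")
            if mask >> n:
                raise RangeTableError(
                    f"taxon {taxon!r} uses an area beyond the {n} declared"
                )

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, taxon: str) -> int:
        return self.masks[taxon]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            taxon: [(mask >> i) & 1 for i in range(len(self.area_labels))]
            for taxon, mask in self.masks.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=self.area_labels
        )

    def validate_against(self, tree: Phylogeny) -> None:
        missing = [t for t in tree.tip_labels if t not in self.masks]
        extra = [t for t in self.masks if t not in set(tree.tip_labels)]
        if missing or extra:
            raise RangeTableError(
                f"range table does not match the tree's tips "
                f"(missing: {missing[:5]}, extra: {extra[:5]})"
            )


def read_tree(path, require_ultrametric: bool = True) -> Phylogeny:
    """Parse a Newick file into a dated :class:`Phylogeny`.

    Validates binary topology and (by default) ultrametricity within a
    relative tolerance of the root age, naming the worst-offending tip.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise TreeError(f"{path}: empty tree file")
    return Phylogeny.from_newick(text, require_ultrametric=require_ultrametric)


def write_tree(tree: Phylogeny, path, precision: int = 10) -> None:
    Path(path).write_text(tree.to_newick(precision=precision) + "\n")


def _sniff_dialect(lines: list[str]) -> str:
    head = lines[0].split()
    if len(head) == 2 and all(tok.isdigit() for tok in head):
        return "lagrange"
    return "tabular"


def read_ranges(
    path, area_labels: list[str], dialect: str = "auto", strip_whitespace: bool = False
) -> TipRangeTable:
    """Read a range table in either dialect into bitmasks over ``area_labels``."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise RangeTableError(f"{path}: empty range table")
    if dialect == "auto":
        dialect = _sniff_dialect(lines)
    if dialect not in ("tabular", "lagrange"):
        raise RangeTableError(f"unknown range-table dialect {dialect!r}")
    masks: dict[str, int] = {}

    def add(taxon: str, bits: list[int], where: str) -> None:
        if strip_whitespace:
            taxon = taxon.strip()
        if taxon in masks:
            raise RangeTableError(f"{where}: duplicate taxon {taxon!r}")
        if len(bits) != len(area_labels):
            raise RangeTableError(
                f"{where}: expected {len(area_labels)} presence flags, "
                f"got {len(bits)}"
            )
        mask = sum(1 << i for i, b in enumerate(bits) if b)
        if mask == 0:
            raise RangeTableError(f"{where}: taxon {taxon!r} occupies no area")
        masks[taxon] = mask

    if dialect == "lagrange":
        ntaxa, nareas = (int(tok) for tok in lines[0].split())
        if nareas != len(area_labels):
            raise RangeTableError(
                f"header declares {nareas} areas but the geography has "
                f"{len(area_labels)}"
            )
        body = lines[1:]
        if len(body) != ntaxa:
            raise RangeTableError(
                f"header declares {ntaxa} taxa but {len(body)} rows follow"
            )
        for i, ln in enumerate(body):
            taxon, bitstring = ln.split(None, 1)
            bitstring = bitstring.strip()
            if not set(bitstring) <= {"0", "1"}:
                raise RangeTableError(f"row {i + 2}: malformed bitstring {bitstring!r}")
            add(taxon, [int(c) for c in bitstring], f"row {i + 2}")
    else:
        header = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
        if header[0].lower() not in ("taxon", "taxa", "species"):
            raise RangeTableError(
                "tabular dialect requires a header starting with 'taxon'"
            )
        cols = header[1:]
        unknown = [c for c in cols if c not in area_labels]
        if unknown:
            raise RangeTableError(f"unknown area label(s) in header: {unknown}")
        if set(cols) != set(area_labels):
            raise RangeTableError(
                f"header areas {cols} do not cover the geography's "
                f"{area_labels}"
            )
        order = [cols.index(lab) for lab in area_labels]
        for i, ln in enumerate(lines[1:]):
            fields = ln.split("\t") if "\t" in ln else ln.split()
            taxon, vals = fields[0], fields[1:]
            if len(vals) != len(cols):
                raise RangeTableError(f"row {i + 2}: wrong number of columns")
            try:
                bits_raw = [int(v) for v in vals]
            except ValueError:
                raise RangeTableError(
                    f"row {i + 2}: presence flags must be 0/1"
                ) from None
            if any(b not in (0, 1) for b in bits_raw):
                raise RangeTableError(f"row {i + 2}: presence flags must be 0/1")
            add(taxon, [bits_raw[j] for j in order], f"row {i + 2}")
    return TipRangeTable(area_labels=list(area_labels), masks=masks)


def write_ranges(
    table: TipRangeTable | dict, path, area_labels=None, dialect: str = "tabular"
) -> None:
    """Write a range table; round-trips with :func:`read_ranges`."""
    if isinstance(table, dict):
        table = TipRangeTable(area_labels=list(area_labels), masks=dict(table))
    labs = table.area_labels
    lines: list[str] = []
    if dialect == "lagrange":
        lines.append(f"{len(table.masks)} {len(labs)}")
        for taxon, mask in table.masks.items():
            bits = "".join(str((mask >> i) & 1) for i in range(len(labs)))
            lines.append(f"{taxon} {bits}")
    elif dialect == "tabular":
        lines.append("\t".join(["taxon"] + labs))
        for taxon, mask in table.masks.items():
            bits = [str((mask >> i) & 1) for i in range(len(labs))]
            lines.append("\t".join([taxon] + bits))
    else:
        raise RangeTableError(f"unknown range-table dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Geography configuration (YAML/JSON)
# ----------------------------------------------------------------------

def _geography_to_dict(geo: Geography) -> dict:
    return {
        "areas": [
            {
                "label": a.label,
                "availability": None if a.availability_age == ALWAYS else a.availability_age,
            }
            for a in geo.areas
        ],
        "events": [{"name": e.name, "age": e.age} for e in geo.events],
        "distance_classes": np.asarray(geo.distance_classes).tolist(),
        "slice_distance_overrides": [
            {"window": [y, o], "matrix": np.asarray(m).tolist()}
            for y, o, m in geo.slice_distance_overrides
        ],
        "tiers": {str(k): v for k, v in geo.tiers.items()},
        "epsilon": geo.epsilon,
        "corridors": [
            {
                "between": [c.area_a, c.area_b],
                "window": [c.young_age, c.old_age],
                "multiplier": c.multiplier,
            }
            for c in geo.corridors
        ],
    }


def _geography_from_dict(cfg: dict) -> Geography:
    try:
        areas = [
            Area(
                a["label"],
                i,
                ALWAYS if a.get("availability") in (None, "always") else float(a["availability"]),
            )
            for i, a in enumerate(cfg["areas"])
        ]
        events = [PaleoEvent(e["name"], float(e["age"])) for e in cfg.get("events", [])]
        overrides = [
            (float(o["window"][0]), float(o["window"][1]), np.asarray(o["matrix"]))
            for o in cfg.get("slice_distance_overrides", [])
        ]
        corridors = [
            Corridor(
                c["between"][0],
                c["between"][1],
                float(c["window"][0]),
                float(c["window"][1]),
                float(c.get("multiplier", 1.0)),
            )
            for c in cfg.get("corridors", [])
        ]
        tiers = {int(k): float(v) for k, v in cfg.get("tiers", {}).items()} or None
        geo = Geography(
            areas=areas,
            events=events,
            distance_classes=(
                np.asarray(cfg["distance_classes"])
                if cfg.get("distance_classes") is not None
                else None
            ),
            slice_distance_overrides=overrides,
            tiers=tiers or {0: 1.0, 1: 0.5, 2: 0.1},
            epsilon=float(cfg.get("epsilon", 0.01)),
            corridors=corridors,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise GeographyError(f"malformed geography config: {exc!r}") from exc
    return geo


def load_geography(path) -> Geography:
    """Load a geography/model config from YAML or JSON."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise GeographyError(f"{path}: config must be a mapping")
    return _geography_from_dict(cfg)


def dump_geography(geo: Geography, path) -> None:
    path = Path(path)
    data = _geography_to_dict(geo)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def config_digest(*parts) -> str:
    """Stable short digest over config dicts/strings, for provenance blocks."""
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Geography):
            p = _geography_to_dict(p)
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def log(message: str) -> None:
    """Diagnostics go to standard error; results go to files/stdout."""
    print(message, file=sys.stderr)
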