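"""Session persistence, item (de)serialization, and configuration loading.

Sessions and items travel as JSON; human-edited configuration is YAML.
Every writer/reader pair is a strict round trip, and malformed files raise
:class:`ValidationError` naming the offending field rather than crashing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from . import adaptive as ad
from .shapes import GridItem, MazeItem, PathItem, SequenceItem, ShapeMatchingItem


class ValidationError(ValueError):
    """A session/item/config file violates the expected schema."""


# ---------------------------------------------------------------------------
# Item JSON


def item_to_dict(item) -> dict:
    """Serialize any game item to its JSON-ready dict (schema: docs/methods.md)."""
    if isinstance(item, GridItem):
        return {
            "game": item.game,
            "rows": item.rows,
            "cols": item.cols,
            "cells": [c for row in item.cells for c in row],
        }
    if isinstance(item, ShapeMatchingItem):
        d = item_to_dict(item.base)
        d["missing_cell"] = list(item.missing_cell)
        d["answer"] = item.answer
        return d
    if isinstance(item, SequenceItem):
        return {"game": item.game, "shapes": list(item.shapes)}
    if isinstance(item, PathItem):
        return {
            "game": item.game,
            "grid_dim": item.grid_dim,
            "nodes": [list(n) for n in item.nodes],
            "endpoints": [list(item.nodes[0]), list(item.nodes[-1])],
        }
    if isinstance(item, MazeItem):
        return {
            "game": item.game,
            "dim": item.dim,
            "open_walls": sorted(sorted(map(list, w)) for w in item.open_walls),
            "start": list(item.start),
            "end": list(item.end),
        }
    raise ValidationError(f"cannot serialize {type(item).__name__}")


def item_from_dict(d: dict):
    """Inverse of :func:`item_to_dict`; validates structure and shape ids."""
    try:
        game = d["game"]
    except (KeyError, TypeError):
        raise ValidationError("item: missing field 'game'") from None
    try:
        if game in ("assembly", "spatial_memory"):
            rows, cols = d["rows"], d["cols"]
            flat = d["cells"]
            cells = [list(flat[r * cols : (r + 1) * cols]) for r in range(rows)]
            return GridItem(rows=rows, cols=cols, cells=cells, game=game)
        if game == "shape_matching":
            rows, cols = d["rows"], d["cols"]
            flat = d["cells"]
            cells = [list(flat[r * cols : (r + 1) * cols]) for r in range(rows)]
            base = GridItem(rows=rows, cols=cols, cells=cells, game=game)
            return ShapeMatchingItem(
                base=base, missing_cell=tuple(d["missing_cell"]), answer=d["answer"]
            )
        if game == "sequence_memory":
            return SequenceItem(shapes=list(d["shapes"]))
        if game == "path_tracking":
            return PathItem(nodes=[tuple(n) for n in d["nodes"]], grid_dim=d.get("grid_dim", 5))
        if game == "maze":
            return MazeItem(
                dim=d["dim"],
                open_walls={frozenset(map(tuple, w)) for w in d["open_walls"]},
                start=tuple(d["start"]),
                end=tuple(d["end"]),
            )
    except ValidationError:
        raise
    except KeyError as exc:
        raise ValidationError(f"item ({game}): missing field {exc}") from None
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"item ({game}): {exc}") from None
    raise ValidationError(f"item: unknown game {game!r}")


# ---------------------------------------------------------------------------
# Session JSON

_RECORD_FIELDS = {"index", "target_c", "c_play", "correct", "completion_time", "score", "breakdown"}


def session_to_dict(log: ad.SessionLog) -> dict:
    return {
        "meta": {
            "game": log.game,
            "mode": log.mode,
            "seed": log.seed,
            "config": log.config,
        },
        "records": [asdict(r) for r in log.records],
        "final_c": log.final_c,
        "total_score": log.total_score,
    }


def session_from_dict(d: dict) -> ad.SessionLog:
    try:
        meta = d["meta"]
        records = []
        for i, r in enumerate(d["records"]):
            unknown = set(r) - _RECORD_FIELDS
            if unknown:
                raise ValidationError(f"records[{i}]: unknown fields {sorted(unknown)}")
            records.append(ad.ItemRecord(**r))
        log = ad.SessionLog(
            game=meta["game"],
            mode=meta["mode"],
            seed=meta.get("seed"),
            records=records,
            final_c=d["final_c"],
            total_score=d["total_score"],
            config=meta.get("config", {}),
        )
    except ValidationError:
        raise
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"session: malformed file ({exc})") from None
    if log.total_score != sum(r.score for r in log.records):
        raise ValidationError("session: total_score does not equal the sum of record scores")
    return log


def write_session(log: ad.SessionLog, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session_to_dict(log), indent=2) + "\n")


def read_session(path: str | Path) -> ad.SessionLog:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"session: not valid JSON ({exc})") from None
    return session_from_dict(d)


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict[str, Any] = {
    "complexity": {
        "m_faces": 6,
        "sigmoid_alpha": 1.0,
        "sigmoid_beta": 2.0,
        "maze_scale": 0.4,
        "maze_inner_scale": 10.0,
    },
    "generator": {"e": 0.25, "max_iterations": 5000, "dims": 3},
    "adaptive": {
        "start_c": 1.0,
        "ceiling_c": 8.0,
        "up_step": 0.5,
        "min_step": 0.05,
        "max_items": 25,
    },
    "player": {
        "slope": 1.5,
        "base_time": 5.0,
        "time_slope": 2.0,
        "time_noise_sd": 1.0,
    },
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults overlaid by a YAML file overlaid by explicit overrides.

    Unknown sections or keys are rejected with the offending key path;
    values must match the type of the default they replace.
    """
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}

    def merge(layer: dict, origin: str) -> None:
        if not isinstance(layer, dict):
            raise ValidationError(f"{origin}: top level must be a mapping")
        for section, values in layer.items():
            if section not in cfg:
                raise ValidationError(f"{origin}: unknown section {section!r}")
            if not isinstance(values, dict):
                raise ValidationError(f"{origin}: section {section!r} must be a mapping")
            for key, value in values.items():
                if key not in cfg[section]:
                    raise ValidationError(f"{origin}: unknown key {section}.{key}")
                default = cfg[section][key]
                if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
                    raise ValidationError(
                        f"{origin}: {section}.{key} must be numeric, got {type(value).__name__}"
                    )
                cfg[section][key] = value

    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            merge(loaded, str(path))
    if overrides:
        merge(overrides, "overrides")
    return cfg
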