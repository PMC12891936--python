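"""Result serialization: CSV tables with JSON provenance manifests.

Every saved table is accompanied by ``<name>.manifest.json`` recording
the parameters, seeds and package version that produced it, so any
result file can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .model import SimParams

__all__ = ["save_results", "load_results", "manifest_path"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def manifest_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".manifest.json")


def save_results(
    table: pd.DataFrame,
    path: str | Path,
    params: SimParams | None = None,
    seeds: list[int] | None = None,
    extra: dict[str, Any] | None = None,
    force: bool = False,
) -> Path:
    """Write a long-format CSV plus a JSON manifest.

    Refuses to overwrite an existing file unless ``force`` is set.
    """
    from . import __version__

    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    manifest = {
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "params": _jsonable(params) if params is not None else None,
        "seeds": seeds,
        "columns": list(table.columns),
        "n_rows": int(len(table)),
    }
    if extra:
        manifest.update(_jsonable(extra))
    manifest_path(path).write_text(json.dumps(manifest, indent=2))
    return path


def load_results(path: str | Path) -> tuple[pd.DataFrame, dict[str, Any] | None]:
    """Read back a saved table and its manifest (None if absent)."""
    path = Path(path)
    table = pd.read_csv(path)
    mpath = manifest_path(path)
    manifest = json.loads(mpath.read_text()) if mpath.exists() else None
    return table, manifest
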