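"""JSON-primary reports with TSV convenience twins.

Every report embeds the effective configuration and the library version so
a run can be reproduced from its own output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return obj


def write_report(out_dir: str | Path, name: str, config: dict, results,
                 tsv_rows: list[dict] | None = None) -> Path:
    """Write ``<name>.json`` (and ``<name>.tsv`` when rows are given)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": _jsonable(config), "results": _jsonable(results)}
    json_path = out_dir / f"{name}.json"
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    if tsv_rows:
        cols = list(tsv_rows[0].keys())
        lines = ["\t".join(cols)]
        for row in tsv_rows:
            lines.append("\t".join(str(_jsonable(row.get(c, ""))) for c in cols))
        (out_dir / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    return json_path
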