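"""Machine-readable evaluation reports.

Results are emitted as JSON (stable metric keys: IM, ACVC, CM, ACC, RE, SCC,
MRD, NRMSE, PET; Sen, Pre, F1, PDR, redundancy) and flat TSV, with floats at
6 significant digits and a versioned schema. Each report records the seed and
a hash of the run configuration so a run is reproducible from its report.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

SCHEMA_VERSION = "1.0"


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if obj == 0:
            return 0.0
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def config_hash(config: Mapping[str, Any]) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def render_report(
    results: Mapping[str, Any],
    out_json: Path,
    out_tsv: Optional[Path] = None,
    config: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
) -> Dict[str, Any]:
    """Write a results mapping as JSON (and optionally flat TSV).

    Returns the serialized document. Nested sections are flattened with
    dotted keys in the TSV.
    """
    doc: Dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    if seed is not None:
        doc["seed"] = seed
    if config is not None:
        doc["config_hash"] = config_hash(config)
    doc["results"] = _round_floats(dict(results))

    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)
    out_json.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    if out_tsv is not None:
        rows = []

        def _flatten(prefix: str, obj: Any) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    _flatten(f"{prefix}.{k}" if prefix else str(k), v)
            else:
                rows.append((prefix, obj))

        _flatten("", doc["results"])
        with open(out_tsv, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, val in rows:
                fh.write(f"{key}\t{val}\n")
    return doc
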