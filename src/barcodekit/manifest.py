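"""Reproducibility manifest written alongside every CLI run's outputs."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path,
    subcommand: str,
    arguments: Mapping,
    input_files: Sequence = (),
) -> Path:
    """Serialize the run manifest: subcommand, full argument map, tool
    version, timestamps, and SHA-256 digests of the input files.

    Identical inputs and arguments produce identical manifests except for
    the timestamp fields.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "barcodekit",
        "version": __version__,
        "subcommand": subcommand,
        "arguments": {k: str(v) if isinstance(v, Path) else v
                      for k, v in sorted(arguments.items())},
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            str(p): _digest(Path(p)) for p in input_files if Path(p).is_file()
        },
    }
    out_path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return out_path
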