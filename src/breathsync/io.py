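"""Plain-text keypress logs, trace CSV, and run manifests.

Keypress log format: one event per line, ``<timestamp_seconds>\\t<I|E>``,
timestamps in seconds from trial start.  The reader tolerates CRLF and
blank lines, skips unparseable lines with a warning, and rejects
out-of-order timestamps; the writer is bit-stable for identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .breath_tracking import OnsetEvent, OnsetKind

logger = logging.getLogger("breathsync")

_KIND_CODE = {OnsetKind.INHALE: "I", OnsetKind.EXHALE: "E"}
_CODE_KIND = {"I": OnsetKind.INHALE, "E": OnsetKind.EXHALE}


def write_keypress_log(events: list[OnsetEvent], path) -> None:
    lines = [f"{e.time:.6f}\t{_KIND_CODE[e.kind]}" for e in events]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_keypress_log(path) -> list[OnsetEvent]:
    """Parse a keypress log; skip bad lines, reject non-monotone stamps.

    Raises ``ValueError`` for an empty file (no parsable events).
    """
    events: list[OnsetEvent] = []
    n_bad = n_nonmono = 0
    last_t = -1.0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            t = float(parts[0])
            kind = _CODE_KIND[parts[1].strip().upper()]
        except (IndexError, KeyError, ValueError):
            n_bad += 1
            logger.warning("%s:%d: unparseable line skipped: %r", path, lineno, raw)
            continue
        if t <= last_t:
            n_nonmono += 1
            logger.warning("%s:%d: out-of-order timestamp %s rejected", path, lineno, t)
            continue
        events.append(OnsetEvent(time=t, kind=kind))
        last_t = t
    if n_nonmono:
        logger.warning("%s: %d out-of-order lines rejected", path, n_nonmono)
    if not events:
        raise ValueError(f"no parsable events in {path}")
    return events


def write_trace_csv(trace, path) -> None:
    trace.to_csv(path, index=False, float_format="%.6f")


def config_hash(config_dict: dict) -> str:
    """Stable SHA-256 of a canonical JSON rendering of the config."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, config_dict: dict, seed: int, outputs: list[str]) -> None:
    """Record everything needed to reconstruct a run."""
    import numpy

    from . import __version__

    manifest = {
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "seed": seed,
        "outputs": sorted(outputs),
        "versions": {"breathsync": __version__, "numpy": numpy.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
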