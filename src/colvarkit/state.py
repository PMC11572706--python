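"""Checkpoint state documents.

A state document is canonical JSON (sorted keys, fixed separators) holding
the step counter, coordinates, velocities, the serialized random-generator
state, every bias's internal state (grids, hill logs, couplings, extended
variables) and, for bias-exchange runs, the bias-to-replica permutation.
Floats are serialized with shortest-round-trip repr, so write -> read ->
write reproduces identical bytes and a restarted run continues
bitwise-identically.
"""

from __future__ import annotations

import json

__all__ = ["FORMAT_VERSION", "write_state", "read_state", "StateError"]

FORMAT_VERSION = 1


class StateError(ValueError):
    pass


def write_state(sim, extra: dict | None = None) -> str:
    """Serialize a Simulation checkpoint to canonical JSON text."""
    doc = {"format": "colvarkit-state", "version": FORMAT_VERSION}
    doc.update(sim.checkpoint())
    if extra:
        doc["extra"] = extra
    return json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"


def read_state(text: str, sim=None) -> dict:
    """Parse a state document; optionally restore it into a Simulation.

    Raises :class:`StateError` on truncated or foreign input or on a
    format-version mismatch — never restores a partial state.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StateError(f"corrupt or truncated state document: {exc}") from exc
    if doc.get("format") != "colvarkit-state":
        raise StateError("not a colvarkit state document")
    if doc.get("version") != FORMAT_VERSION:
        raise StateError(f"state format version {doc.get('version')} "
                         f"not supported (expected {FORMAT_VERSION})")
    if sim is not None:
        sim.restore(doc)
    return doc
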