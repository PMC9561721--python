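"""Structured (JSON-lines) event logging.

Every droppable event in the pipeline -- dropped rows, symbol collisions,
compatibility flags -- goes through :func:`log_event` so that runs are
auditable from the log stream alone.
"""
from __future__ import annotations

import json
import logging

logger = logging.getLogger("sigportrait")


def log_event(event: str, **fields) -> None:
    """Emit one JSON object per event on the package logger."""
    payload = {"event": event}
    payload.update(fields)
    logger.info(json.dumps(payload, sort_keys=True, default=str))
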