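"""Leakage instrumentation.

Every fitting routine in the package reports the patient ids it consumed via
:func:`record_fit_rows`.  Wrapping a pipeline run in :func:`capture_fit_rows`
collects them, so a test (or a cautious user) can assert that no fit call
ever touched a held-out row.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Iterator

_ACTIVE: list[list[tuple[str, frozenset]]] = []


def record_fit_rows(stage: str, patient_ids: Iterable[str]) -> None:
    """Report that ``stage`` fit on ``patient_ids`` (no-op unless capturing)."""
    if _ACTIVE:
        ids = frozenset(patient_ids)
        for sink in _ACTIVE:
            sink.append((stage, ids))


@contextlib.contextmanager
def capture_fit_rows() -> Iterator[list[tuple[str, frozenset]]]:
    """Collect ``(stage, patient_ids)`` records from every fit call inside."""
    sink: list[tuple[str, frozenset]] = []
    _ACTIVE.append(sink)
    try:
        yield sink
    finally:
        _ACTIVE.remove(sink)
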