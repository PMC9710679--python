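"""Genomic-neighbourhood estimation (gne).

The 20 kbp intergenic-distance default is arbitrary and can be inappropriate
for loosely clustered genomes (plants especially). gne re-runs cluster
detection on a saved session over a range of gap values — never re-running
the homology search — and tabulates, at each value, the total number of
predicted clusters and the mean and median cluster size in bp. Plotted,
these curves typically resemble logarithmic growth; stable plateaus suggest
gap values that avoid liminal regions where small changes in the threshold
would swing the output.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import replace
from typing import Sequence

import numpy as np

from .datamodel import GneRow, ParameterError, Session
from .detect import detect_all

logger = logging.getLogger("clusterseek")

DEFAULT_MAX_GAP = 100000
DEFAULT_SAMPLES = 100


def gap_values(max_gap: int, samples: int, scale: str = "linear") -> list[int]:
    """Ordered gap values to sweep.

    linear: ``samples`` evenly spaced integers from 0 to ``max_gap``.
    log:    ``samples`` geometrically spaced integers from 1 to ``max_gap``
            with the first point replaced by 0, so the degenerate gap is
            always sampled.
    Duplicate values after integer rounding are collapsed.
    """
    if samples < 2:
        raise ParameterError(f"samples must be >= 2, got {samples}")
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    if scale == "linear":
        raw = np.linspace(0, max_gap, samples)
    elif scale == "log":
        if max_gap == 0:
            return [0]
        raw = np.geomspace(1, max_gap, samples)
        raw[0] = 0
    else:
        raise ParameterError(f"scale must be linear|log, got {scale!r}")
    values: list[int] = []
    for v in raw:
        iv = int(round(float(v)))
        if not values or iv > values[-1]:
            values.append(iv)
    return values


def compute_gne(
    session: Session,
    max_gap: int = DEFAULT_MAX_GAP,
    samples: int = DEFAULT_SAMPLES,
    scale: str = "linear",
) -> list[GneRow]:
    """Sweep detection over gap values and tabulate cluster statistics.

    All detection parameters except the gap come from the session. Cluster
    size is ``end - start`` in bp; mean and median run over every emitted
    cluster in every organism, and are 0 when no cluster is emitted. The
    session's stored clusters are left untouched.
    """
    rows: list[GneRow] = []
    for gap in gap_values(max_gap, samples, scale):
        params = replace(session.detect, gap=gap)
        clusters = detect_all(session, params)
        sizes = [c.span for c in clusters]
        rows.append(GneRow(
            gap=gap,
            total_clusters=len(sizes),
            mean_size=float(statistics.mean(sizes)) if sizes else 0.0,
            median_size=float(statistics.median(sizes)) if sizes else 0.0,
        ))
    return rows


def gne_table(rows: Sequence[GneRow], delimiter: str = "\t") -> str:
    """Delimited table of gne rows: gap, total clusters, mean and median size."""
    lines = [delimiter.join(("gap", "total_clusters", "mean_size", "median_size"))]
    for row in rows:
        lines.append(delimiter.join((
            str(row.gap), str(row.total_clusters),
            f"{row.mean_size:.1f}", f"{row.median_size:.1f}")))
    return "\n".join(lines) + "\n"
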