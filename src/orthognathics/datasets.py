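"""Bundled reference data.

A ten-patient clinical reference cohort of bimaxillary-surgery outcomes
(planned-to-postoperative discrepancies per segment, in this tool's reporting
convention) ships with the package for demonstration and regression use.
Values are stored verbatim as exported (including one decimal-comma cell,
which exercises the reader's normalisation).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .frames import MovementReport
from .io import parse_number

__all__ = ["load_reference_cohort", "REFERENCE_SEGMENTS"]

REFERENCE_SEGMENTS = ("maxilla", "mandible_distal")


def load_reference_cohort(segment_id: str = "maxilla") -> list[MovementReport]:
    """Per-patient planned-vs-achieved movement reports for one segment.

    ``segment_id`` is ``"maxilla"`` or ``"mandible_distal"`` (the distal,
    tooth-bearing mandibular segment).  Returns ten reports ordered by
    patient number.
    """
    if segment_id not in REFERENCE_SEGMENTS:
        raise ValueError(
            f"no reference cohort for {segment_id!r}; available: "
            f"{REFERENCE_SEGMENTS}")
    ref = resources.files("orthognathics.data") \
        .joinpath(f"reference_cohort_{segment_id}.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    reports = []
    for _, row in df.iterrows():
        reports.append(MovementReport(
            segment_id=segment_id,
            **{c: parse_number(row[c]) for c in MovementReport.COMPONENTS}))
    return reports
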