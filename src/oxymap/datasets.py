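"""Packaged example data: longitudinal bowel SO2 profiles and transection
decisions for seven colon segments, used as phantom ground truth."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_so2_profiles", "load_transection_decisions"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("oxymap.data") / name
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_so2_profiles() -> pd.DataFrame:
    """Per-segment SO2 (%) at ten 1 cm axial positions, proximal to distal.

    Columns: ``position_cm`` plus one column per segment (P1..P7).
    """
    return _read("bowel_so2_profiles.tsv")


def load_transection_decisions() -> pd.DataFrame:
    """Surgeon-chosen transection position (cm) per segment."""
    return _read("transection_decisions.tsv")
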