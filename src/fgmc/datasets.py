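"""Accessors for the packaged reference data.

Two small tables ship with the package: the 29-country survey reference
table (prevalence, customary age window, type-III shares) and the 2013
per-country register group counts.  Suppressed cells of the published counts
are reconstructed from the printed margins; see the data files' headers for
which cells are exact and which are synthetic allocations.
"""

from __future__ import annotations

import io
from importlib import resources

from .cohort_classifier import GroupCounts
from .country_profiles import ProfileSet, load_profiles

__all__ = ["reference_profiles", "group_counts_2013"]


def reference_profiles() -> ProfileSet:
    """The packaged 29-country reference table, loaded and validated."""
    return load_profiles()


def group_counts_2013() -> GroupCounts:
    """Published 2013 register group counts (suppressed cells reconstructed)."""
    text = resources.files("fgmc.data").joinpath("group_counts_2013.csv").read_text("utf-8")
    return GroupCounts.from_csv(io.StringIO(text))
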