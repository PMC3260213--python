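"""Target-group pseudo-absences for presence-only modelling.

Banding data records where surveyed birds were, never where they were
absent, and survey effort is far from uniform.  Drawing background points
from the locations of the *other* study species — wherever the focal
species was not recorded — gives pseudo-absences that share the survey's
spatial bias, so the model contrasts habitat rather than effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .banding import EncounterRecord
from .grid import CellIndex
from .seasons import SeasonWindows, assign_season

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presences and candidate background cells of one species-season."""

    species: str
    season: str
    presence_cells: set
    background_cells: set

    def __post_init__(self) -> None:
        overlap = self.presence_cells & self.background_cells
        if overlap:
            raise ValueError(
                f"presence and background cells overlap ({len(overlap)} shared)"
            )


def presence_cells(
    records: Iterable[EncounterRecord],
    species: str,
    season: str,
    windows: SeasonWindows,
) -> set:
    """Unique cells of all events of a species within its season window."""
    cells = {
        r.cell
        for r in records
        if r.species == species
        and r.cell is not None
        and assign_season(r.date, windows) == season
    }
    if not cells:
        logger.warning("no %s events of %s in season window", season, species)
    return cells


def target_group_background(
    records: Sequence[EncounterRecord],
    focal: str,
    season: str,
    windows_by_species: Mapping[str, SeasonWindows],
) -> set:
    """Known locations of other study species where the focal one is absent.

    Every non-focal species contributes its presence cells for the given
    season evaluated under *its own* season windows; the focal species'
    presence cells (under its windows) are removed.
    """
    others = {r.species for r in records} - {focal}
    if not others:
        raise ValueError("target-group background needs at least one non-focal species")
    candidates: set = set()
    for sp in others:
        candidates |= presence_cells(records, sp, season, windows_by_species[sp])
    candidates -= presence_cells(records, focal, season, windows_by_species[focal])
    if not candidates:
        raise ValueError(
            f"no background candidates for {focal}/{season}: the focal species "
            "occupies every surveyed cell; broaden the record set"
        )
    return candidates


def sample_background(candidates: Iterable[CellIndex], n: int, seed: int) -> set:
    """Uniform sample of n cells without replacement; deterministic in seed."""
    if n <= 0:
        raise ValueError("background sample size must be positive")
    pool = sorted(candidates)
    if not pool:
        raise ValueError("empty candidate set")
    if n >= len(pool):
        if n > len(pool):
            logger.warning(
                "requested %d background cells but only %d candidates; taking all",
                n,
                len(pool),
            )
        return set(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in idx}
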