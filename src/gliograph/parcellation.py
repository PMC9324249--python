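"""Synthetic brain parcellation tables.

A parcellation assigns every region of interest (ROI) a hemisphere (L/R, with
M reserved for midline structures) and an anatomical lobe.  The default table
mimics a 136-parcel whole-brain atlas split evenly between hemispheres, with
lobe sizes allocated by fixed fractions.  Homotopic pairing (the left/right
mirror of a region) is implied by sharing a lobe and within-lobe index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

LOBES = ("frontal", "temporal", "parietal", "insular", "occipital", "other")

#: Default per-hemisphere share of parcels per lobe, loosely matching the
#: relative parcel counts of a whole-brain anatomical atlas.
DEFAULT_LOBE_FRACTIONS: dict[str, float] = {
    "frontal": 0.30,
    "temporal": 0.25,
    "parietal": 0.20,
    "occipital": 0.15,
    "insular": 0.06,
    "other": 0.04,
}


@dataclass(frozen=True)
class ParcellationTable:
    """ROI labels with hemisphere and lobe assignments.

    The wrapped frame has columns ``roi_id`` (0-based, contiguous), ``name``,
    ``hemisphere`` (one of L/R/M) and ``lobe``.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        expected = ["roi_id", "name", "hemisphere", "lobe"]
        if list(df.columns) != expected:
            raise InvalidArgumentError(f"parcellation columns must be {expected}")
        ids = df["roi_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise InvalidArgumentError("roi_ids must be unique, contiguous and 0-based")
        if not df["hemisphere"].isin(["L", "R", "M"]).all():
            raise InvalidArgumentError("hemisphere must be one of L, R, M")
        if not df["lobe"].isin(LOBES).all():
            raise InvalidArgumentError(f"lobe must be one of {LOBES}")

    @property
    def n_roi(self) -> int:
        return len(self.frame)

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        """roi_ids belonging to one hemisphere."""
        mask = self.frame["hemisphere"] == hemisphere
        return self.frame.loc[mask, "roi_id"].to_numpy()

    def lobe_ids(self, lobe: str, hemisphere: str | None = None) -> np.ndarray:
        """roi_ids of a lobe, optionally restricted to one hemisphere."""
        mask = self.frame["lobe"] == lobe
        if hemisphere is not None:
            mask &= self.frame["hemisphere"] == hemisphere
        return self.frame.loc[mask, "roi_id"].to_numpy()

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """(left_id, right_id) pairs matched by (lobe, within-lobe index)."""
        pairs = []
        for lobe in LOBES:
            left = self.lobe_ids(lobe, "L")
            right = self.lobe_ids(lobe, "R")
            for l_id, r_id in zip(left, right):
                pairs.append((int(l_id), int(r_id)))
        return pairs

    def lobe_of(self) -> np.ndarray:
        return self.frame["lobe"].to_numpy()

    def hemisphere_of(self) -> np.ndarray:
        return self.frame["hemisphere"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcellationTable":
        return cls(pd.read_csv(path, sep="\t"))


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Deterministic integer allocation of ``n`` seats by fractional quota."""
    total = sum(fractions.values())
    quotas = {k: n * v / total for k, v in fractions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    # Ties broken by fixed lobe order for determinism.
    order = sorted(fractions, key=lambda k: (-(quotas[k] - counts[k]), LOBES.index(k)))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def make_parcellation(
    n_roi: int = 136,
    lobe_fractions: dict[str, float] | None = None,
) -> ParcellationTable:
    """Build a deterministic parcellation with an even hemisphere split.

    Parameters
    ----------
    n_roi:
        Total number of regions; must be an even number >= 4 so the
        left/right split is exact.
    lobe_fractions:
        Per-lobe share of parcels within each hemisphere.  Defaults to
        :data:`DEFAULT_LOBE_FRACTIONS`.
    """
    if n_roi < 4:
        raise InvalidArgumentError("n_roi must be >= 4")
    if n_roi % 2 != 0:
        raise InvalidArgumentError("n_roi must be even for an exact hemisphere split")
    fractions = dict(lobe_fractions or DEFAULT_LOBE_FRACTIONS)
    unknown = set(fractions) - set(LOBES)
    if unknown:
        raise InvalidArgumentError(f"unknown lobes in fractions: {sorted(unknown)}")
    per_hemi = n_roi // 2
    counts = _largest_remainder(per_hemi, fractions)

    rows = []
    roi_id = 0
    for hemisphere in ("L", "R"):
        for lobe in LOBES:
            for k in range(counts.get(lobe, 0)):
                rows.append(
                    {
                        "roi_id": roi_id,
                        "name": f"{hemisphere}_{lobe}_{k:02d}",
                        "hemisphere": hemisphere,
                        "lobe": lobe,
                    }
                )
                roi_id += 1
    return ParcellationTable(pd.DataFrame(rows, columns=["roi_id", "name", "hemisphere", "lobe"]))
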