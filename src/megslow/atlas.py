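"""90-region parcellation of source space.

The pipeline works on region-of-interest (ROI) time series labelled by an
AAL-style atlas with 78 cortical and 12 subcortical regions.  Downstream
reductions (cortical vs. subcortical averages) depend only on the region
count and on the cortical/subcortical partition, never on region geometry,
so the atlas is a plain ordered label list with a group flag per region.

Indices are 0-based everywhere inside the package; user-facing reports
(e.g. permutation edge lists) use 1-based region numbers, matching the
convention that regions 1-78 are cortical and 79-90 subcortical in the
default ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

N_REGIONS = 90
N_CORTICAL = 78
N_SUBCORTICAL = 12

_VALID_GROUPS = ("cortical", "subcortical")


class AtlasError(ValueError):
    """Raised when an atlas definition violates the 90 = 78 + 12 contract."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of 90 region labels with a cortical/subcortical flag each.

    Parameters
    ----------
    labels : tuple of str
        Region names, order preserved from the source file.
    group : tuple of str
        Per-region flag, each ``"cortical"`` or ``"subcortical"``.
    """

    labels: tuple[str, ...]
    group: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != N_REGIONS:
            raise AtlasError(
                f"expected {N_REGIONS} regions, got {len(self.labels)}"
            )
        if len(self.group) != len(self.labels):
            raise AtlasError("labels and group flags differ in length")
        for i, g in enumerate(self.group):
            if g not in _VALID_GROUPS:
                raise AtlasError(
                    f"line {i + 1}: unknown group flag {g!r} "
                    f"(expected one of {_VALID_GROUPS})"
                )
        seen: dict[str, int] = {}
        for i, lab in enumerate(self.labels):
            if lab in seen:
                raise AtlasError(
                    f"line {i + 1}: duplicate label {lab!r} "
                    f"(first seen on line {seen[lab] + 1})"
                )
            seen[lab] = i
        n_cort = sum(g == "cortical" for g in self.group)
        if n_cort != N_CORTICAL:
            raise AtlasError(
                f"expected {N_CORTICAL} cortical and {N_SUBCORTICAL} "
                f"subcortical regions, got {n_cort} cortical"
            )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def cortical_indices(self) -> np.ndarray:
        """0-based indices of the 78 cortical regions."""
        return np.flatnonzero(np.asarray(self.group) == "cortical")

    @property
    def subcortical_indices(self) -> np.ndarray:
        """0-based indices of the 12 subcortical regions."""
        return np.flatnonzero(np.asarray(self.group) == "subcortical")


def load_atlas(source: str | Path | None = None) -> RegionAtlas:
    """Load a region atlas from a tab-separated file, or the packaged default.

    The file format is one region per line, ``<label><TAB><cortical|subcortical>``,
    90 lines.  With ``source=None`` the packaged AAL-style list is used, which
    orders the 78 cortical regions first (positions 1-78) and the 12
    subcortical regions last (79-90).

    Raises
    ------
    AtlasError
        On a wrong region count, an unknown group flag, or duplicate labels;
        the message names the offending line.
    """
    if source is None:
        text = (
            resources.files("megslow.data").joinpath("aal90.tsv").read_text()
        )
    else:
        text = Path(source).read_text()
    labels: list[str] = []
    groups: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AtlasError(
                f"line {lineno}: expected '<label><TAB><group>', got {raw!r}"
            )
        label, grp = parts[0].strip(), parts[1].strip()
        if grp not in _VALID_GROUPS:
            raise AtlasError(
                f"line {lineno}: unknown group flag {grp!r} "
                f"(expected one of {_VALID_GROUPS})"
            )
        labels.append(label)
        groups.append(grp)
    if len(labels) != N_REGIONS:
        raise AtlasError(
            f"expected {N_REGIONS} regions, file defines {len(labels)}"
        )
    return RegionAtlas(tuple(labels), tuple(groups))


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    """Write an atlas in the same tab-separated format read by `load_atlas`."""
    with open(path, "w") as fh:
        for label, grp in zip(atlas.labels, atlas.group):
            fh.write(f"{label}\t{grp}\n")


def region_groups(atlas: RegionAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Return (cortical, subcortical) 0-based index arrays.

    The two sets are disjoint and together cover all 90 indices; this
    partition property is guaranteed by atlas validation.
    """
    return atlas.cortical_indices, atlas.subcortical_indices
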