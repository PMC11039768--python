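"""Network atlas: mapping of ROIs onto large-scale resting-state networks.

The default atlas covers eleven regions of interest spanning the default
mode network (DMN, 2 ROIs: medial prefrontal cortex and posterior
cingulate), the salience network (SN, 5 ROIs: bilateral anterior insula,
dorsal anterior cingulate, bilateral nucleus accumbens) and the
frontoparietal network (FPN, 4 ROIs: bilateral dorsolateral prefrontal
cortex and bilateral intraparietal sulcus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

NETWORK_LABELS = ("DMN", "SN", "FPN")


class AtlasError(ValueError):
    """Raised for malformed atlas definitions."""


@dataclass(frozen=True)
class NetworkAtlas:
    """Ordered ROI list plus the network label of each ROI.

    ``roi_names`` fixes the canonical column order of every time-series
    matrix in a run; ``network_of`` maps each ROI name to one of
    ``NETWORK_LABELS``.
    """

    roi_names: tuple[str, ...]
    network_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            dupes = {r for r in self.roi_names if list(self.roi_names).count(r) > 1}
            raise AtlasError(f"duplicate ROI name(s): {sorted(dupes)}")
        if set(self.network_of) != set(self.roi_names):
            raise AtlasError("network_of keys must match roi_names exactly")
        bad = {r: n for r, n in self.network_of.items() if n not in NETWORK_LABELS}
        if bad:
            raise AtlasError(f"unknown network label(s): {bad}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def network_sizes(self) -> dict[str, int]:
        sizes = {n: 0 for n in NETWORK_LABELS}
        for r in self.roi_names:
            sizes[self.network_of[r]] += 1
        return {n: c for n, c in sizes.items() if c > 0}

    def networks_of_indices(self) -> list[str]:
        """Network label per ROI, in column order."""
        return [self.network_of[r] for r in self.roi_names]

    def index_of(self, roi: str) -> int:
        return self.roi_names.index(roi)


#: ROI -> network for the 11-node DMN/SN/FPN atlas used throughout.
_DEFAULT_ATLAS_ROWS = (
    ("mPFC", "DMN"),
    ("PCC", "DMN"),
    ("L_AI", "SN"),
    ("R_AI", "SN"),
    ("dACC", "SN"),
    ("L_NAcc", "SN"),
    ("R_NAcc", "SN"),
    ("L_DLPFC", "FPN"),
    ("R_DLPFC", "FPN"),
    ("L_IPS", "FPN"),
    ("R_IPS", "FPN"),
)


def default_atlas() -> NetworkAtlas:
    """The packaged 11-ROI atlas (DMN=2, SN=5, FPN=4)."""
    names = tuple(r for r, _ in _DEFAULT_ATLAS_ROWS)
    return NetworkAtlas(roi_names=names, network_of=dict(_DEFAULT_ATLAS_ROWS))
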