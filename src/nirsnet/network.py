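"""ROI-level functional brain networks from channel-pair coherence.

The 22 prefrontal channels map onto 10 regions of interest (left/right
frontopolar area FOA, orbitofrontal area OFA, pars triangularis Broca's
area PTBA, dorsolateral prefrontal cortex DLPFC, inferior prefrontal gyrus
IPFG). Two channels sit on the hemispheric midline and belong to both the
left and right instance of their region (CH04 in L/RFOA, CH19 in L/ROFA).

The edge between two regions is the mean band WPCO over their constituent
channel pairs, with pairs that failed the surrogate validity test entering
as zero (default) or excluded (``mode="valid-only"``). If no constituent
pair is valid the edge is zero — connectivity that does not beat the
surrogate null does not enter the network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PairCoherence
from .recording import DEFAULT_CHANNELS

__all__ = ["ROI_ORDER", "RoiMap", "RoiNetwork", "load_roi_map", "aggregate", "to_edgelist"]

#: Canonical ROI ordering used for matrices and outputs.
ROI_ORDER = (
    "LFOA", "RFOA", "LOFA", "ROFA", "LPTBA",
    "RPTBA", "LDLPFC", "RDLPFC", "LIPFG", "RIPFG",
)


@dataclass(frozen=True)
class RoiMap:
    """Mapping from ROI label to its set of measurement channels."""

    rois: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = set(ROI_ORDER) - set(self.rois)
        if missing:
            raise ValueError(f"missing ROI(s): {sorted(missing)}")
        extra = set(self.rois) - set(ROI_ORDER)
        if extra:
            raise ValueError(f"unknown ROI label(s): {sorted(extra)}")
        valid = set(DEFAULT_CHANNELS)
        for roi, chans in self.rois.items():
            unknown = set(chans) - valid
            if unknown:
                raise ValueError(f"{roi}: unknown channel label(s) {sorted(unknown)}")
        covered = set().union(*self.rois.values())
        uncovered = valid - covered
        if uncovered:
            raise ValueError(f"channels not assigned to any ROI: {sorted(uncovered)}")

    def __getitem__(self, roi: str) -> frozenset[str]:
        return self.rois[roi]

    def cross_pairs(self, roi_a: str, roi_b: str) -> set[frozenset[str]]:
        """Unordered channel pairs linking two ROIs (shared channels count once)."""
        return {
            frozenset((p, q))
            for p in self.rois[roi_a]
            for q in self.rois[roi_b]
            if p != q
        }

    def within_pairs(self, roi: str) -> set[frozenset[str]]:
        return {
            frozenset(pq) for pq in itertools.combinations(sorted(self.rois[roi]), 2)
        }


def load_roi_map(source: str | Path | None = None) -> RoiMap:
    """Load the shipped channel→ROI fixture, or a user JSON of the same schema.

    The schema is ``{"ROI": ["CHxx", ...], ...}`` with exactly the ten
    canonical ROI labels and channels from the 22-channel montage.
    """
    if source is None:
        text = (resources.files("nirsnet") / "data" / "roi_map.json").read_text()
    else:
        text = Path(source).read_text()
    raw = json.loads(text)
    return RoiMap(rois={roi: frozenset(chans) for roi, chans in raw.items()})


@dataclass
class RoiNetwork:
    """Symmetric 10x10 ROI coherence matrix with zero diagonal.

    ``intra`` holds the mean within-ROI coherence for regions with more
    than one channel (kept off the diagonal by convention). ``absent``
    flags ROI pairs with no constituent channel pair (cannot occur with the
    canonical map, but user maps may create them).
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    intra: dict[str, float] = field(default_factory=dict)
    absent: np.ndarray | None = None
    mode: str = "zero"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if (self.matrix < -1e-9).any() or (self.matrix > 1 + 1e-9).any():
            raise ValueError("edge weights must lie in [0, 1]")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")

    def edge(self, roi_a: str, roi_b: str) -> float:
        return float(
            self.matrix[self.labels.index(roi_a), self.labels.index(roi_b)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def aggregate(
    pairs: list[PairCoherence],
    roi_map: RoiMap,
    mode: str = "zero",
    provenance: dict | None = None,
) -> RoiNetwork:
    """Aggregate channel-pair coherence into the ROI network.

    Parameters
    ----------
    pairs
        Channel-pair results covering every pair of the montage.
    roi_map
        The channel→ROI mapping.
    mode
        ``"zero"`` (default): invalid pairs contribute 0 to the mean —
        the strict reading of the zeroing rule. ``"valid-only"``: average
        only the valid pairs (0 if none is valid).
    """
    if mode not in ("zero", "valid-only"):
        raise ValueError("mode must be 'zero' or 'valid-only'")
    lookup: dict[frozenset[str], PairCoherence] = {
        frozenset(p.channels): p for p in pairs
    }

    def pooled(chan_pairs: set[frozenset[str]]) -> float:
        vals = []
        for pq in chan_pairs:
            try:
                p = lookup[pq]
            except KeyError:
                a, b = sorted(pq)
                raise ValueError(f"channel pair {a}-{b} missing from input") from None
            if mode == "zero":
                vals.append(p.band_wpco if p.valid else 0.0)
            elif p.valid:
                vals.append(p.band_wpco)
        return float(np.mean(vals)) if vals else 0.0

    n = len(ROI_ORDER)
    matrix = np.zeros((n, n))
    absent = np.zeros((n, n), dtype=bool)
    for (i, roi_a), (j, roi_b) in itertools.combinations(enumerate(ROI_ORDER), 2):
        chan_pairs = roi_map.cross_pairs(roi_a, roi_b)
        if not chan_pairs:
            absent[i, j] = absent[j, i] = True
            continue
        matrix[i, j] = matrix[j, i] = pooled(chan_pairs)
    intra = {
        roi: pooled(roi_map.within_pairs(roi))
        for roi in ROI_ORDER
        if len(roi_map[roi]) > 1
    }
    return RoiNetwork(
        labels=ROI_ORDER,
        matrix=matrix,
        intra=intra,
        absent=absent,
        mode=mode,
        provenance=provenance or {},
    )


def to_edgelist(net: RoiNetwork, threshold: float = 0.0) -> pd.DataFrame:
    """Edge list (roi_a, roi_b, weight) for weights above ``threshold``."""
    rows = [
        {"roi_a": a, "roi_b": b, "weight": net.edge(a, b)}
        for a, b in itertools.combinations(net.labels, 2)
        if net.edge(a, b) > threshold
    ]
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "weight"])


def plot_heatmap(net: RoiNetwork, path: str | Path) -> None:
    """Save the adjacency matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(net.matrix, vmin=0, vmax=max(net.matrix.max(), 1e-9), cmap="viridis")
    ax.set_xticks(range(len(net.labels)), net.labels, rotation=90)
    ax.set_yticks(range(len(net.labels)), net.labels)
    fig.colorbar(im, ax=ax, label="band WPCO")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
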