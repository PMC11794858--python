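"""Parcellation atlas: ROI table with resting-state network labels.

The atlas fixes the edge indexing used everywhere downstream: edges are
the strict upper triangle of the ROI x ROI matrix, enumerated row-major,
so edge e <-> ROI pair (i, j), i < j.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AtlasError

#: The eight canonical resting-state networks plus subcortex.
NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
    "subcortical",
)

HEMISPHERES = ("L", "R", "midline")


def n_edges(P: int) -> int:
    """Number of distinct ROI pairs for a P-region atlas: P(P-1)/2.

    A 246-region parcellation yields 30,135 edges.
    """
    if not isinstance(P, (int, np.integer)) or P < 2:
        raise AtlasError(f"atlas must have at least 2 ROIs, got P={P!r}")
    return P * (P - 1) // 2


@dataclass(frozen=True)
class Atlas:
    """ROI table: id, name, hemisphere, and one network label per region.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``roi_id`` (1..P, contiguous), ``roi_name``,
        ``hemisphere`` (L/R/midline), ``network`` (one of :data:`NETWORKS`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["roi_id", "roi_name", "hemisphere", "network"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise AtlasError(f"atlas table missing columns: {missing}")
        P = len(t)
        if P < 2:
            raise AtlasError(f"atlas must have at least 2 ROIs, got {P}")
        ids = t["roi_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(1, P + 1)):
            raise AtlasError("roi_id must be unique and contiguous 1..P")
        bad_net = sorted(set(t["network"]) - set(NETWORKS))
        if bad_net:
            raise AtlasError(f"unknown network label(s): {bad_net}")
        bad_hemi = sorted(set(t["hemisphere"]) - set(HEMISPHERES))
        if bad_hemi:
            raise AtlasError(f"unknown hemisphere label(s): {bad_hemi}")
        # normalize row order to roi_id
        object.__setattr__(self, "table", t.sort_values("roi_id").reset_index(drop=True))

    @property
    def P(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        return n_edges(self.P)

    @property
    def networks(self) -> np.ndarray:
        """Network label per ROI, in roi_id order."""
        return self.table["network"].to_numpy()

    def network_indices(self) -> dict[str, np.ndarray]:
        """0-based ROI indices per network (only networks present)."""
        nets = self.networks
        return {n: np.flatnonzero(nets == n) for n in NETWORKS if (nets == n).any()}

    def edge_networks(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge network labels of the two endpoint ROIs (i<j order)."""
        iu, ju = np.triu_indices(self.P, k=1)
        nets = self.networks
        return nets[iu], nets[ju]


def make_atlas(network_sizes: dict[str, int]) -> Atlas:
    """Construct a synthetic atlas with the given per-network ROI counts.

    Regions are named ``<NET>_<i>_<hemi>`` with alternating hemispheres;
    useful for tests and scaled-down simulations.
    """
    bad = set(network_sizes) - set(NETWORKS)
    if bad:
        raise AtlasError(f"unknown network label(s): {sorted(bad)}")
    rows = []
    rid = 1
    for net, size in network_sizes.items():
        for i in range(size):
            hemi = "L" if i % 2 == 0 else "R"
            rows.append((rid, f"{net[:3].upper()}_{i // 2 + 1}_{hemi}", hemi, net))
            rid += 1
    return Atlas(pd.DataFrame(rows, columns=["roi_id", "roi_name", "hemisphere", "network"]))


def default_atlas() -> Atlas:
    """The bundled 246-region default atlas.

    The ROI-to-network assignment shipped here is a synthetic stand-in
    with realistic per-network region counts; analyses of real cohorts
    should supply the lab's own parcellation table.
    """
    with resources.files("fcbiotype.data").joinpath("atlas246_synthetic.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return Atlas(table)
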