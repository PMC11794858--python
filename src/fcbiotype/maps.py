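"""Parcellated neurotransmitter density maps.

Each map is a P-length vector of mean tracer density per ROI, already
projected onto the analysis parcellation; metadata records tracer and
provenance. Volumetric PET images are out of scope — node vectors are
the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError


@dataclass
class MapTable:
    """P x n_maps density table plus per-map metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        One column per map, P rows (ROI order of the atlas).
    metadata : dict
        map_name -> free-form metadata (tracer, source, ...).
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise FormatError(f"missing values in map column(s): {bad}")
        extra = set(self.metadata) - set(self.values.columns)
        if extra:
            raise FormatError(f"metadata for unknown map(s): {sorted(extra)}")

    @property
    def P(self) -> int:
        return len(self.values)

    @property
    def map_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_maps(self) -> int:
        return self.values.shape[1]

    def vector(self, map_name: str) -> np.ndarray:
        return self.values[map_name].to_numpy(dtype=float)

    def check_atlas(self, P: int) -> None:
        if self.P != P:
            raise DimensionError(f"map table has {self.P} rows but atlas has P={P} ROIs")
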