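"""Simulated third-party relay: row alignment and one-shot latent aggregation.

The relay's only jobs are (1) making sure the i-th row at every site refers
to the same individual and (2) concatenating the sites' code matrices
column-wise for the central server.  The exchange happens once per model
build — the relay is a pure function over in-memory latent datasets, not a
server loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autoencoder import LatentDataset
from .errors import AlignmentError, InputError

__all__ = ["AlignmentResult", "AggregatedLatent", "align", "aggregate"]


@dataclass
class AlignmentResult:
    """Aligned latent datasets plus the count of rows each site lost."""

    latents: list[LatentDataset]
    dropped_per_site: list[int]

    def __iter__(self):
        return iter(self.latents)


@dataclass
class AggregatedLatent:
    """Row-aligned column-wise concatenation of all sites' latent matrices.

    ``provenance`` maps each aggregate column index to its origin
    (site_index, code index); sites appear as contiguous blocks in
    ascending site_index order.
    """

    row_ids: np.ndarray
    matrix: np.ndarray
    provenance: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.row_ids = np.asarray(self.row_ids)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[1] != len(self.provenance):
            raise InputError("provenance length must equal aggregate width")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def site_indices(self) -> list[int]:
        seen: list[int] = []
        for s, _ in self.provenance:
            if not seen or seen[-1] != s:
                seen.append(s)
        return seen

    def site_block(self, site_index: int) -> np.ndarray:
        """The sub-matrix contributed by one site (bit-identical slice)."""
        cols = [i for i, (s, _) in enumerate(self.provenance) if s == site_index]
        if not cols:
            raise InputError(f"no columns from site {site_index}")
        return self.matrix[:, cols]

    def to_csv(self, path) -> None:
        cols = [f"s{s}_c{c:03d}" for s, c in self.provenance]
        frame = pd.DataFrame(self.matrix, columns=cols)
        frame.insert(0, "row_id", self.row_ids)
        frame.to_csv(path, index=False)

    def provenance_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"columns": [{"site": s, "code": c} for s, c in self.provenance]},
                fh,
            )


def align(latents: list[LatentDataset]) -> AlignmentResult:
    """Reorder every site's latent rows to the sorted intersection of row IDs.

    Rows absent from any site are dropped; the per-site drop counts are
    returned alongside the aligned datasets.  An empty intersection is an
    :class:`AlignmentError`.
    """
    if not latents:
        raise InputError("align needs at least one latent dataset")
    common = None
    for lat in latents:
        ids = set(lat.row_ids.tolist())
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise AlignmentError("no row IDs shared by all sites")
    order = np.array(sorted(common))
    aligned, dropped = [], []
    for lat in latents:
        pos = {rid: i for i, rid in enumerate(lat.row_ids.tolist())}
        take = np.array([pos[rid] for rid in order.tolist()])
        aligned.append(LatentDataset(lat.site_index, order.copy(), lat.codes[take]))
        dropped.append(lat.n_rows - len(order))
    return AlignmentResult(aligned, dropped)


def aggregate(latents: list[LatentDataset]) -> AggregatedLatent:
    """Concatenate aligned latent matrices column-wise, ascending site order.

    Inputs must already share identical row IDs in identical order (call
    :func:`align` first otherwise); duplicate site indices are rejected.
    """
    if not latents:
        raise InputError("aggregate needs at least one latent dataset")
    sites = [lat.site_index for lat in latents]
    if len(set(sites)) != len(sites):
        raise InputError(f"duplicate site_index among inputs: {sorted(sites)}")
    ordered = sorted(latents, key=lambda lat: lat.site_index)
    first = ordered[0]
    for lat in ordered[1:]:
        if len(lat.row_ids) != len(first.row_ids) or not np.array_equal(
            lat.row_ids, first.row_ids
        ):
            raise AlignmentError(
                "row IDs differ across sites; run align() before aggregate()"
            )
    matrix = np.concatenate([lat.codes for lat in ordered], axis=1)
    provenance = [
        (lat.site_index, c) for lat in ordered for c in range(lat.code_dim)
    ]
    return AggregatedLatent(first.row_ids.copy(), matrix, provenance)
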