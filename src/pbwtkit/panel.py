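"""Haplotype panels: M phased binary sequences over N ordered variant sites.

A panel is the unit of input for every algorithm in this package.  Alleles
are coded 0 (reference) / 1 (alternate); multi-allelic sites and missing
data are rejected at construction because every downstream algorithm
assumes exact bi-allelic matching.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PanelError

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class HaplotypePanel:
    """An M x N matrix of phased binary haplotypes.

    Parameters
    ----------
    alleles:
        Array-like of shape (M, N) with values in {0, 1}.  Row ``i`` is
        haplotype sequence ``x_i``; column ``k`` is variant site ``k``.
    sites:
        Optional table of site metadata with columns ``chrom``, ``pos``,
        ``ref``, ``alt``.  Positions must be strictly increasing within a
        chromosome.
    sample_names:
        Optional per-haplotype labels (two per diploid sample, e.g.
        ``NA12878_h1`` / ``NA12878_h2``).
    """

    def __init__(
        self,
        alleles: np.ndarray | Sequence[Sequence[int]] | Sequence[str],
        sites: pd.DataFrame | None = None,
        sample_names: Sequence[str] | None = None,
    ):
        if (
            isinstance(alleles, (list, tuple))
            and len(alleles) > 0
            and isinstance(alleles[0], str)
        ):
            alleles = [[int(ch) for ch in row] for row in alleles]
        arr = np.asarray(alleles)
        if arr.ndim != 2:
            raise PanelError(f"allele matrix must be 2-D, got shape {arr.shape}")
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))].ravel()[0]
            raise PanelError(f"alleles must be 0 or 1; found {bad!r}")
        self.alleles = np.ascontiguousarray(arr, dtype=np.uint8)

        if sites is not None:
            sites = pd.DataFrame(sites).reset_index(drop=True)
            missing = [c for c in SITE_COLUMNS if c not in sites.columns]
            if missing:
                raise PanelError(f"site table missing columns {missing}")
            if len(sites) != self.N:
                raise PanelError(
                    f"site table has {len(sites)} rows but panel has {self.N} sites"
                )
            for _, grp in sites.groupby("chrom", sort=False):
                pos = grp["pos"].to_numpy()
                if np.any(np.diff(pos) <= 0):
                    raise PanelError(
                        "site positions must be strictly increasing within a chromosome"
                    )
        self.sites = sites

        if sample_names is not None:
            sample_names = list(sample_names)
            if len(sample_names) != self.M:
                raise PanelError(
                    f"{len(sample_names)} sample names for {self.M} haplotypes"
                )
        self.sample_names = sample_names

    # -- basic geometry -------------------------------------------------

    @property
    def M(self) -> int:
        """Number of haplotype sequences."""
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        """Number of variant sites."""
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray | None:
        """Base-pair positions, or None when no site table is attached."""
        if self.sites is None:
            return None
        return self.sites["pos"].to_numpy()

    def sequence(self, i: int) -> np.ndarray:
        return self.alleles[i]

    def column(self, k: int) -> np.ndarray:
        return self.alleles[:, k]

    def iter_columns(self):
        """Yield site columns in original haplotype order (streaming view)."""
        for k in range(self.N):
            yield self.alleles[:, k]

    # -- derived panels --------------------------------------------------

    def subset_sequences(self, indices: Sequence[int]) -> "HaplotypePanel":
        """Keep a subset of haplotype rows; the site list is unchanged."""
        idx = np.asarray(indices, dtype=np.intp)
        names = (
            [self.sample_names[i] for i in idx] if self.sample_names is not None else None
        )
        return HaplotypePanel(self.alleles[idx], sites=self.sites, sample_names=names)

    def subset_sites(self, mask_or_indices) -> "HaplotypePanel":
        """Keep a subset of sites, preserving order."""
        sel = np.asarray(mask_or_indices)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        sites = self.sites.iloc[sel] if self.sites is not None else None
        return HaplotypePanel(
            self.alleles[:, sel], sites=sites, sample_names=self.sample_names
        )

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the 1 allele at each site."""
        if self.M == 0:
            return np.zeros(self.N)
        return self.alleles.mean(axis=0)

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return self.alleles.shape == other.alleles.shape and bool(
            np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return f"HaplotypePanel(M={self.M}, N={self.N}, sites={self.sites is not None})"


def default_sites(positions, chrom: str = "1") -> pd.DataFrame:
    """Minimal site table from bare positions (synthetic panels, text input)."""
    pos = np.asarray(positions, dtype=np.int64)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"},
        columns=list(SITE_COLUMNS),
    )
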