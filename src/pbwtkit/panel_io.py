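"""Reading and writing haplotype panels, queries and match streams.

Supported dialects:

* VCF/BCF with phased GT fields (two haplotype rows per diploid sample,
  named ``<sample>_h1`` / ``<sample>_h2``);
* site-major 0/1 text: one line per site, optionally preceded by a
  position column (extra leading fields are ignored);
* sequence-major 0/1 text: one line of N characters per sequence (this
  is also the raw-text dialect used for gzip baselines);
* tab-separated match lines ``seq_a  seq_b  start  end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PanelError
from .matching import Match
from .panel import SITE_COLUMNS, HaplotypePanel, default_sites

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_region(region: str):
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo) if lo else None, int(hi) if hi else None


def read_vcf(
    source, region: str | None = None, drop_unphased: bool = False
) -> HaplotypePanel:
    """Load phased biallelic SNVs from a VCF/BCF into a panel.

    Multi-allelic and non-SNV records are skipped with a logged count.
    Unphased heterozygous or missing genotypes abort by default
    (exactness is the method's premise); ``drop_unphased=True`` drops
    the offending sites instead.  ``region`` is ``chrom`` or
    ``chrom:start-end`` (1-based, inclusive).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(source))
    samples = list(vcf.samples)
    if not samples:
        raise PanelError("VCF has no samples")
    want = _parse_region(region) if region else None

    rows: list[np.ndarray] = []
    recs: list[tuple] = []
    n_skipped_alleles = 0
    n_dropped_unphased = 0
    for v in vcf:
        if want is not None:
            chrom, lo, hi = want
            if v.CHROM != chrom:
                continue
            if lo is not None and v.POS < lo:
                continue
            if hi is not None and v.POS > hi:
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped_alleles += 1
            continue
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        site = np.empty(2 * len(samples), dtype=np.int16)
        bad = None
        for s, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                bad = f"missing genotype for sample {samples[s]}"
                break
            if not phased and a0 != a1:
                bad = f"unphased heterozygote {a0}/{a1} for sample {samples[s]}"
                break
            site[2 * s] = a0
            site[2 * s + 1] = a1
        if bad is not None:
            if drop_unphased:
                n_dropped_unphased += 1
                continue
            raise PanelError(f"{v.CHROM}:{v.POS}: {bad}")
        rows.append(site.astype(np.uint8))
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_skipped_alleles:
        logger.info("skipped %d multi-allelic or non-SNV records", n_skipped_alleles)
    if n_dropped_unphased:
        logger.info("dropped %d sites with unphased/missing genotypes", n_dropped_unphased)
    if not rows:
        raise PanelError("no biallelic SNV records found")
    alleles = np.stack(rows, axis=1)  # (2*n_samples, N)
    names = [f"{s}_h{h}" for s in samples for h in (1, 2)]
    sites = pd.DataFrame(recs, columns=list(SITE_COLUMNS))
    return HaplotypePanel(alleles, sites=sites, sample_names=names)


# ---------------------------------------------------------------------------
# text dialects
# ---------------------------------------------------------------------------


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    return [ln for ln in text.splitlines() if ln.strip()]


def _parse_allele_string(s: str, lineno: int) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    if arr.size and not np.isin(arr, (0, 1)).all():
        ch = s[int(np.flatnonzero(~np.isin(arr, (0, 1)))[0])]
        raise PanelError(f"line {lineno}: illegal character {ch!r} in alleles")
    return arr


def read_sitemajor_text(source) -> HaplotypePanel:
    """One line per site: optional leading fields, optional position
    column immediately before the alleles, then M characters in {0,1}."""
    lines = _read_lines(source)
    if not lines:
        raise PanelError("empty site-major input")
    cols = []
    positions: list[float] | None = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        alleles = _parse_allele_string(tokens[-1], lineno)
        if cols and alleles.shape[0] != cols[0].shape[0]:
            raise PanelError(
                f"line {lineno}: {alleles.shape[0]} alleles, expected {cols[0].shape[0]}"
            )
        cols.append(alleles)
        if positions is not None and len(tokens) >= 2:
            try:
                positions.append(float(tokens[-2]))
            except ValueError:
                positions = None
        else:
            positions = None
    alleles = np.stack(cols, axis=1)  # (M, N)
    sites = None
    if positions is not None:
        pos = np.round(np.asarray(positions)).astype(np.int64)
        if pos.size == 1 or np.all(np.diff(pos) > 0):
            sites = default_sites(pos)
    return HaplotypePanel(alleles, sites=sites)


def read_matrix_text(source) -> HaplotypePanel:
    """One line of N characters in {0,1} per haplotype sequence."""
    lines = _read_lines(source)
    if not lines:
        raise PanelError("empty matrix input")
    rows = []
    for lineno, line in enumerate(lines, start=1):
        row = _parse_allele_string(line.strip(), lineno)
        if rows and row.shape[0] != rows[0].shape[0]:
            raise PanelError(
                f"line {lineno}: ragged row of {row.shape[0]} alleles, "
                f"expected {rows[0].shape[0]}"
            )
        rows.append(row)
    return HaplotypePanel(np.stack(rows, axis=0))


def write_matrix_text(panel: HaplotypePanel, destination) -> None:
    """Write the sequence-major dialect (the gzip-baseline text)."""
    lines = []
    for i in range(panel.M):
        lines.append((panel.alleles[i] + ord("0")).tobytes().decode())
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def write_sitemajor_text(panel: HaplotypePanel, destination) -> None:
    """Write the site-major dialect, with a position column when the
    panel carries a site table."""
    pos = panel.positions
    lines = []
    for k in range(panel.N):
        alleles = (panel.alleles[:, k] + ord("0")).tobytes().decode()
        lines.append(f"{int(pos[k])} {alleles}" if pos is not None else alleles)
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteFilterSpec:
    """Random thinning of sites above a minor-allele-frequency threshold
    (emulates reducing sequence data to genotyping-array density)."""

    keep_fraction: float = 0.1
    min_maf: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.keep_fraction <= 1:
            raise PanelError("keep_fraction must be in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise PanelError("min_maf must be in [0, 0.5)")


def filter_sites(panel: HaplotypePanel, spec: SiteFilterSpec) -> HaplotypePanel:
    """Keep each site with minor-allele frequency > min_maf with
    probability keep_fraction (seeded), preserving site order."""
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    rng = np.random.default_rng(spec.seed)
    draws = rng.random(panel.N)
    keep = (maf > spec.min_maf) & (draws < spec.keep_fraction)
    return panel.subset_sites(keep)


# ---------------------------------------------------------------------------
# match output
# ---------------------------------------------------------------------------


def write_matches(
    matches: Iterable[Match],
    destination,
    labels: Sequence[str] | None = None,
    header: bool = False,
    query_labels: Sequence[str] | None = None,
) -> int:
    """Write matches as tab-separated ``seq_a seq_b start end`` lines.

    ``labels`` maps panel indices (column seq_b, and seq_a too unless
    ``query_labels`` is given) to sample_hap identifiers.  Returns the
    number of matches written.
    """

    def name(idx: int, lab) -> str:
        if lab is None:
            return str(idx)
        try:
            return lab[idx]
        except IndexError:
            raise PanelError(f"no label for sequence index {idx}") from None

    a_labels = query_labels if query_labels is not None else labels
    own = not hasattr(destination, "write")
    fh = open(destination, "w") if own else destination
    n = 0
    try:
        if header:
            fh.write("seq_a\tseq_b\tstart\tend\n")
        for m in matches:
            fh.write(
                f"{name(m.seq_a, a_labels)}\t{name(m.seq_b, labels)}"
                f"\t{m.start}\t{m.end}\n"
            )
            n += 1
    finally:
        if own:
            fh.close()
    return n
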