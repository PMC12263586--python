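"""Relative binding affinity of transcription factors from 8-mer PBM tables.

A protein binding microarray (PBM) measures a factor's median signal
intensity against every DNA 8-mer (4^8 = 65,536). The relative affinity of a
candidate binding site is the ratio of the site 8-mer's median intensity to
the factor's optimal (maximum-intensity) 8-mer, giving a score in [0, 1].
Because PBM signal is double-stranded, an 8-mer and its reverse complement
are treated as equivalent: tables are stored reverse-complement expanded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqtools import GenomicInterval, reverse_complement

__all__ = [
    "PBMTable",
    "BindingSite",
    "AffinityMatrix",
    "load_pbm_table",
    "optimal_intensity",
    "relative_affinity",
    "site_relative_affinity",
    "build_affinity_matrix",
    "render_heatmap",
]

log = logging.getLogger(__name__)

FULL_TABLE_SIZE = 4 ** 8           # 65,536 distinct 8-mers
COLLAPSED_TABLE_SIZE = 32_896      # one row per {8mer, revcomp} pair


class PBMError(ValueError):
    """Malformed PBM table or invalid affinity query."""


def _validate_kmer(kmer: str, k: int = 8) -> str:
    kmer = kmer.upper()
    if len(kmer) != k or not set(kmer) <= set("ACGT"):
        raise PBMError(f"invalid {k}-mer {kmer!r}")
    return kmer


@dataclass
class PBMTable:
    """One factor's map from 8-mer to median signal intensity.

    ``intensities`` is reverse-complement expanded: a k-mer and its reverse
    complement always share one value. Complete tables have 65,536 entries.
    """

    factor_name: str
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        for kmer, value in self.intensities.items():
            if value < 0:
                raise PBMError(f"negative intensity for {kmer}: {value}")

    @property
    def is_complete(self) -> bool:
        return len(self.intensities) == FULL_TABLE_SIZE

    def __contains__(self, kmer: str) -> bool:
        return kmer.upper() in self.intensities

    def __getitem__(self, kmer: str) -> float:
        kmer = _validate_kmer(kmer)
        try:
            return self.intensities[kmer]
        except KeyError:
            raise PBMError(
                f"8-mer {kmer} absent from table for {self.factor_name}"
            ) from None


def _expand_rc(raw: dict[str, float], source: str = "") -> dict[str, float]:
    """RC-expand a k-mer map, rejecting conflicting duplicate values."""
    expanded: dict[str, float] = {}
    for kmer, value in raw.items():
        for key in (kmer, reverse_complement(kmer)):
            if key in expanded and not np.isclose(expanded[key], value):
                raise PBMError(
                    f"conflicting intensities for {key} and its reverse "
                    f"complement in {source or 'table'}: "
                    f"{expanded[key]} vs {value}"
                )
            expanded[key] = value
    return expanded


def load_pbm_table(path: str | Path, factor_name: str | None = None) -> PBMTable:
    """Read a UniProbe-style 2-column TSV (8mer, median intensity).

    A header line whose first field is not a valid 8-mer names the factor.
    Collapsed tables (one row per reverse-complement pair) are expanded so an
    8-mer and its reverse complement share one intensity. Parse errors carry
    the offending line number.
    """
    path = Path(path)
    raw: dict[str, float] = {}
    header_factor = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PBMError(f"{path.name}:{lineno}: expected 2 tab-separated "
                               f"columns, got {len(fields)}")
            kmer_field = fields[0].strip().upper()
            if lineno == 1 and (len(kmer_field) != 8
                                or not set(kmer_field) <= set("ACGT")):
                header_factor = fields[1].strip() or fields[0].strip()
                continue
            if len(kmer_field) != 8 or not set(kmer_field) <= set("ACGT"):
                raise PBMError(f"{path.name}:{lineno}: malformed 8-mer "
                               f"{fields[0]!r}")
            try:
                value = float(fields[1])
            except ValueError:
                raise PBMError(f"{path.name}:{lineno}: non-numeric intensity "
                               f"{fields[1]!r}") from None
            if kmer_field in raw and not np.isclose(raw[kmer_field], value):
                raise PBMError(f"{path.name}:{lineno}: duplicate conflicting "
                               f"entry for {kmer_field}")
            raw[kmer_field] = value
    name = factor_name or header_factor or path.stem
    return PBMTable(name, _expand_rc(raw, source=path.name))


def optimal_intensity(table: PBMTable) -> tuple[float, str, bool]:
    """Maximum intensity, its 8-mer, and whether the maximum was tied.

    Ties are broken lexicographically (smallest 8-mer wins) and flagged.
    """
    if not table.intensities:
        raise PBMError(f"empty PBM table for {table.factor_name}")
    best = max(table.intensities.values())
    winners = sorted(k for k, v in table.intensities.items() if v == best)
    tied = len(winners) > 1
    return best, winners[0], tied


def relative_affinity(table: PBMTable, kmer: str) -> float:
    """Intensity of ``kmer`` over the factor's optimal 8-mer, in [0, 1]."""
    value = table[kmer]
    best, _, _ = optimal_intensity(table)
    if best == 0:
        raise PBMError(f"optimal intensity is 0 for {table.factor_name}")
    ratio = value / best
    if ratio > 1.0:
        warnings.warn(
            f"relative affinity {ratio:.4g} > 1 for {kmer} "
            f"({table.factor_name}); clamping", stacklevel=2)
        ratio = 1.0
    return ratio


# ---------------------------------------------------------------------------
# Site scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSite:
    """A candidate binding site within a query sequence (1-based inclusive)."""

    name: str
    interval: GenomicInterval
    core_motif: str = ""


WINDOW_POLICIES = ("overlap6", "contained", "any_overlap")


def _admitted_windows(site: BindingSite, seq_len: int,
                      window_policy: str) -> list[int]:
    """1-based start positions of 8-mer windows admitted for a site."""
    start, end = site.interval.start, site.interval.end
    if not (1 <= start <= end <= seq_len):
        raise PBMError(f"site {site.name} interval {start}-{end} outside "
                       f"sequence of length {seq_len}")
    site_len = end - start + 1
    if window_policy == "overlap6":
        min_overlap = min(6, site_len)
    elif window_policy == "contained":
        if site_len < 8:
            raise PBMError(f"site {site.name} ({site_len} bp) shorter than an "
                           "8-mer; 'contained' policy inapplicable")
        min_overlap = 8
    elif window_policy == "any_overlap":
        min_overlap = 1
    else:
        raise PBMError(f"unknown window policy {window_policy!r}; "
                       f"choose from {WINDOW_POLICIES}")
    starts = []
    for w in range(max(1, start - 8 + min_overlap),
                   min(seq_len - 7, end - min_overlap + 1) + 1):
        overlap = min(w + 7, end) - max(w, start) + 1
        if overlap >= min_overlap:
            starts.append(w)
    if not starts:
        raise PBMError(f"no admissible 8-mer window for site {site.name} "
                       f"under policy {window_policy!r}")
    return starts


def site_relative_affinity(table: PBMTable, sequence: str, site: BindingSite,
                           window_policy: str = "overlap6"
                           ) -> tuple[float, str, str]:
    """Best relative affinity over the 8-mer windows representing a site.

    The default policy admits every 8-base window overlapping the site
    interval by >= 6 bases and scores the maximum; the table's RC expansion
    makes the score strand-symmetric. Returns
    ``(affinity, maximizing 8-mer, strand)`` where strand is '+' unless only
    the reverse-complement key is present in the table.
    """
    sequence = sequence.upper()
    best_val, best_kmer, best_strand = -1.0, "", "+"
    skipped = 0
    for w in _admitted_windows(site, len(sequence), window_policy):
        kmer = sequence[w - 1: w + 7]
        if not set(kmer) <= set("ACGT"):
            skipped += 1
            log.warning("site %s: window at %d contains non-ACGT base; skipped",
                        site.name, w)
            continue
        if kmer in table:
            value, strand = relative_affinity(table, kmer), "+"
        elif reverse_complement(kmer) in table:
            value, strand = relative_affinity(table, reverse_complement(kmer)), "-"
        else:
            raise PBMError(f"8-mer {kmer} absent from table for "
                           f"{table.factor_name}")
        if value > best_val or (value == best_val and kmer < best_kmer):
            best_val, best_kmer, best_strand = value, kmer, strand
    if best_val < 0:
        raise PBMError(f"all windows skipped for site {site.name} "
                       f"(non-ACGT bases)")
    return best_val, best_kmer, best_strand


@dataclass
class AffinityMatrix:
    """TF x binding-site matrix of relative affinities with provenance.

    ``values`` has one row per factor and one column per site; NaN marks a
    cell that could not be scored (reason in ``provenance``).
    ``window_choice`` records the maximizing 8-mer and strand per cell.
    """

    factors: list[str]
    sites: list[str]
    values: np.ndarray
    window_choice: dict[tuple[str, str], tuple[str, str]] = field(
        default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.factors, columns=self.sites)


def build_affinity_matrix(tables: Sequence[PBMTable | None] | Mapping[str, PBMTable | None],
                          sequence: str, sites: Sequence[BindingSite],
                          window_policy: str = "overlap6") -> AffinityMatrix:
    """Assemble the TF x site relative-affinity matrix.

    A ``None`` table (factor with no PBM data, e.g. Hand2) produces an
    explicit all-NA row, never a silent omission; any per-cell failure is
    recorded as NA with its reason rather than raised.
    """
    if isinstance(tables, Mapping):
        named: list[tuple[str, PBMTable | None]] = list(tables.items())
    else:
        named = [(t.factor_name if t is not None else f"factor_{i}", t)
                 for i, t in enumerate(tables)]
    if not named or not sites:
        raise PBMError("need at least one factor and one site")

    factors = [name for name, _ in named]
    site_names = [s.name for s in sites]
    values = np.full((len(named), len(sites)), np.nan)
    matrix = AffinityMatrix(factors, site_names, values)

    for i, (name, table) in enumerate(named):
        for j, site in enumerate(sites):
            key = (name, site.name)
            if table is None:
                matrix.provenance[key] = "no PBM data for factor"
                continue
            try:
                val, kmer, strand = site_relative_affinity(
                    table, sequence, site, window_policy)
            except PBMError as exc:
                matrix.provenance[key] = str(exc)
                continue
            values[i, j] = val
            matrix.window_choice[key] = (kmer, strand)
            matrix.provenance[key] = "ok"
    return matrix


def render_heatmap(matrix: AffinityMatrix, path: str | Path) -> Path:
    """Render the affinity matrix as a white-to-dark-blue heatmap on [0, 1].

    NA cells are hatched. Returns the written path.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("pbm_blue",
                                             ["#ffffff", "#08306b"])
    data = np.ma.masked_invalid(matrix.values)
    n_f, n_s = len(matrix.factors), len(matrix.sites)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * n_s + 2),
                                    max(3, 0.45 * n_f + 1.5)))
    ax.imshow(data, cmap=cmap, vmin=0.0, vmax=1.0, aspect="auto")
    for (i, j), is_masked in np.ndenumerate(np.ma.getmaskarray(data)):
        if is_masked:
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                       fill=False, hatch="///",
                                       edgecolor="grey", linewidth=0))
    ax.set_xticks(range(n_s), matrix.sites, rotation=45, ha="right")
    ax.set_yticks(range(n_f), matrix.factors)
    sm = plt.cm.ScalarMappable(cmap=cmap)
    sm.set_clim(0.0, 1.0)
    fig.colorbar(sm, ax=ax, label="relative affinity")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
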