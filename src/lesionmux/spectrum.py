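"""Pileups and lesion-site miscoding spectra.

The mutation readout of the assay is purely compositional: pile up the
validated inserts over the region of interest, take the base counts at the
lesion coordinate, and report the relative proportion of each canonical
base.  ``mutation_frequency`` is 1 minus the fraction of the cognate
reference base (adenine); mutation-class shares are reported both among
mutant reads (f_T / (1 - f_A)) and among all reads (f_T), since context
figures in this assay family are usually drawn on the all-reads scale.

No sequencing-error correction is applied: proportions are raw, and the
adenine control construct serves as the empirical noise floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constructs import INSERT_LEN, ConstructLayout
from .extract import PASS
from .seqs import DNA_ALPHABET

__all__ = ["pileup", "miscoding", "aggregate", "SpectrumResult",
           "spectra_table", "write_pileup"]


@dataclass
class SpectrumResult:
    """Base composition at the lesion site for one (or one pooled) group."""

    counts: dict[str, float]
    ref_base: str = "A"
    lesion: str | None = None        # base identity, e.g. "oxoeA" or "A"
    construct_id: str | None = None
    context: str | None = None
    genotype: str | None = None
    replicate: str | None = None
    no_coverage: bool = field(init=False, default=False)
    depth: float = field(init=False, default=0.0)
    fractions: dict[str, float] = field(init=False, default_factory=dict)
    mutation_frequency: float | None = field(init=False, default=None)
    mutant_shares: dict[str, float] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_base not in DNA_ALPHABET:
            raise ValueError(f"ref_base must be one of ACGT: {self.ref_base!r}")
        counts = {b: float(self.counts.get(b, 0.0)) for b in DNA_ALPHABET}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"negative counts: {counts}")
        self.counts = counts
        self.depth = sum(counts.values())
        if self.depth == 0:
            self.no_coverage = True
            return
        self.fractions = {b: counts[b] / self.depth for b in DNA_ALPHABET}
        self.mutation_frequency = 1.0 - self.fractions[self.ref_base]
        if self.mutation_frequency > 0:
            mutant = self.depth - counts[self.ref_base]
            self.mutant_shares = {b: counts[b] / mutant
                                  for b in DNA_ALPHABET if b != self.ref_base}

    def key(self) -> tuple:
        return (self.lesion, self.genotype, self.context, self.replicate)

    def to_row(self) -> dict:
        row = {
            "construct_id": self.construct_id, "lesion": self.lesion,
            "context": self.context, "genotype": self.genotype,
            "replicate": self.replicate, "ref_base": self.ref_base,
            "depth": self.depth, "no_coverage": self.no_coverage,
            "mutation_frequency": self.mutation_frequency,
        }
        for b in DNA_ALPHABET:
            row[f"count_{b}"] = self.counts[b]
            row[f"f_{b}"] = self.fractions.get(b)
        for b in DNA_ALPHABET:
            if b != self.ref_base:
                row[f"share_{self.ref_base}to{b}"] = self.mutant_shares.get(b)
        return row


def pileup(observations: pd.DataFrame,
           layout: ConstructLayout,
           *, roi: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-position base counts over the region of interest.

    Counts each PASS insert's bases at the assembled-construct coordinates
    it occupies, clipped to the region of interest; ROI positions outside
    the insert have zero depth.  Returns a frame indexed by
    ``(construct_id, coordinate)`` with columns A, C, G, T, depth.
    """
    roi = roi or layout.region_of_interest
    passed = observations[observations["status"] == PASS]
    if passed.empty:
        warnings.warn("no PASS observations; pileup table is empty")
        return pd.DataFrame(
            columns=list(DNA_ALPHABET) + ["depth"],
            index=pd.MultiIndex.from_arrays([[], []],
                                            names=["construct_id",
                                                   "coordinate"]))
    coords = np.arange(layout.insert_start, layout.insert_end + 1)
    in_roi = (coords >= roi[0]) & (coords <= roi[1])
    frames = []
    for cid, grp in passed.groupby("construct_id", sort=True):
        arr = np.frombuffer("".join(grp["insert_seq"]).encode(),
                            dtype=np.uint8).reshape(-1, INSERT_LEN)
        data = {b: (arr == ord(b)).sum(axis=0)[in_roi]
                for b in DNA_ALPHABET}
        sub = pd.DataFrame(data, index=pd.MultiIndex.from_product(
            [[cid], coords[in_roi]], names=["construct_id", "coordinate"]))
        frames.append(sub)
    table = pd.concat(frames)
    table["depth"] = table[list(DNA_ALPHABET)].sum(axis=1)
    return table


def miscoding(pileup_table: pd.DataFrame,
              lesion_coordinate: int,
              *, ref_base: str = "A",
              construct_id: str | None = None,
              **group_fields) -> SpectrumResult:
    """Lesion-site miscoding fractions from a pileup.

    ``group_fields`` (lesion, context, genotype, replicate) are attached to
    the result for downstream grouping.  Zero depth at the lesion coordinate
    yields a result flagged ``no_coverage`` rather than an error.
    """
    counts = {b: 0.0 for b in DNA_ALPHABET}
    if construct_id is not None:
        sel = (pileup_table.index.get_level_values("construct_id")
               == construct_id)
        sub = pileup_table[sel]
    else:
        sub = pileup_table
    at = sub[sub.index.get_level_values("coordinate") == lesion_coordinate]
    if not at.empty:
        counts = {b: float(at[b].sum()) for b in DNA_ALPHABET}
    result = SpectrumResult(counts=counts, ref_base=ref_base,
                            construct_id=construct_id, **group_fields)
    if result.no_coverage:
        warnings.warn(
            f"no coverage at lesion coordinate {lesion_coordinate} "
            f"(construct {construct_id})")
    return result


def aggregate(spectra: Sequence[SpectrumResult],
              *, allow_mixed_lesion: bool = False,
              **group_fields) -> SpectrumResult:
    """Depth-weighted pooling: sum lesion-site counts, recompute fractions.

    Pooling is associative and order-independent because it operates on raw
    counts.  Pooling across different lesion identities is refused unless
    ``allow_mixed_lesion=True`` (pooling a lesion with its control would
    silently dilute the spectrum).
    """
    if not spectra:
        raise ValueError("nothing to aggregate")
    ref = spectra[0].ref_base
    if any(s.ref_base != ref for s in spectra):
        raise ValueError("cannot pool spectra with different reference bases")
    lesions = {s.lesion for s in spectra}
    if len(lesions) > 1 and not allow_mixed_lesion:
        raise ValueError(
            f"refusing to pool across lesion identities {sorted(map(str, lesions))}; "
            f"pass allow_mixed_lesion=True to override")
    counts = {b: sum(s.counts[b] for s in spectra) for b in DNA_ALPHABET}
    fields = dict(group_fields)
    fields.setdefault("lesion",
                      spectra[0].lesion if len(lesions) == 1 else None)
    return SpectrumResult(counts=counts, ref_base=ref, **fields)


def spectra_table(spectra: Iterable[SpectrumResult]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in spectra])


def write_pileup(pileup_table: pd.DataFrame, path: str | Path) -> None:
    """Write a pileup as a tab-separated table (1-based inclusive coords)."""
    pileup_table.reset_index().to_csv(path, sep="\t", index=False)
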