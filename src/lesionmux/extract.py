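"""From raw read pairs to validated insert observations.

The pipeline stage mirrors the assay's filtering logic: read pairs are
merged by overlap consensus, the 34-mer insert is located between fixed
genomic flank anchors, its length is checked (exactly 18 + 16 nt — anything
else is a ligation artefact), the trinucleotide barcode is matched exactly
against the construct table, and the 16-mer is verified against its template
outside the lesion position.  Every input pair yields exactly one
observation, PASS or a categorised REJECT, so counts always conserve.

Barcode matching is exact by design: trinucleotide barcodes can sit at
Hamming distance 1 from each other, so any mismatch rescue would cause
cross-talk between constructs; ambiguous reads are rejected instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from numpy.lib.stride_tricks import sliding_window_view

from .constructs import (BARCODE_OLIGO_LEN, INSERT_LEN, LESION_OLIGO_LEN,
                         ConstructLayout)
from .errors import ConfigurationError, ConstructDefinitionError
from .seqs import revcomp, to_u8

__all__ = [
    "PASS", "REJECT_MERGE", "REJECT_TEMPLATE", "REJECT_LENGTH",
    "REJECT_BARCODE", "STATUSES", "InsertObservation", "merge_pair",
    "extract_insert", "demux", "extract_observations",
    "write_observations", "read_observations", "status_counts",
]

PASS = "PASS"
REJECT_MERGE = "REJECT_MERGE"
REJECT_TEMPLATE = "REJECT_TEMPLATE"
REJECT_LENGTH = "REJECT_LENGTH"
REJECT_BARCODE = "REJECT_BARCODE"
STATUSES = (PASS, REJECT_MERGE, REJECT_TEMPLATE, REJECT_LENGTH,
            REJECT_BARCODE)

OBS_COLUMNS = ["fragment_id", "status", "construct_id", "context",
               "lesion_base", "barcode", "flank_mismatches",
               "template_mismatches", "insert_seq"]


@dataclass
class InsertObservation:
    """One read pair reduced to a validated insert (or a categorised reject)."""

    fragment_id: str
    status: str
    construct_id: str | None = None
    context: str | None = None
    lesion_base: str | None = None
    barcode: str | None = None
    flank_mismatches: int | None = None
    template_mismatches: int | None = None
    insert_seq: str | None = None


# -- pair merging -----------------------------------------------------------

def merge_pair(seq1: str, qual1: str, seq2: str, qual2: str,
               *, min_overlap: int = 10,
               max_overlap_mismatch: float = 0.1,
               ) -> tuple[str, str] | None:
    """Merge a read pair into an overlap-consensus fragment.

    R2 is reverse-complemented and the largest 3'(R1)/5'(R2) overlap with a
    mismatch fraction <= ``max_overlap_mismatch`` is taken; at discordant
    overlap positions the higher-quality base wins (ties go to R1).  Returns
    ``(sequence, quality)`` or ``None`` when no acceptable overlap of at
    least ``min_overlap`` exists.
    """
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    if not seq1 or not seq2:
        raise ValueError("cannot merge a zero-length read")
    if len(seq1) != len(qual1) or len(seq2) != len(qual2):
        raise ValueError("sequence/quality length mismatch")
    b_seq = revcomp(seq2)
    b_qual = qual2[::-1]
    a = to_u8(seq1)
    b = to_u8(b_seq)
    la, lb = len(seq1), len(b_seq)
    for o in range(min(la, lb), min_overlap - 1, -1):
        mism = int(np.count_nonzero(a[la - o:] != b[:o]))
        if mism <= max_overlap_mismatch * o:
            return _consensus(seq1, qual1, b_seq, b_qual, o)
    return None


def _consensus(seq1: str, qual1: str, b_seq: str, b_qual: str,
               o: int) -> tuple[str, str]:
    la = len(seq1)
    head_s, head_q = seq1[:la - o], qual1[:la - o]
    tail_s, tail_q = b_seq[o:], b_qual[o:]
    ov_s = list(seq1[la - o:])
    ov_q = list(qual1[la - o:])
    for i in range(o):
        # Phred+33 chars compare like the scores they encode.
        if b_qual[i] > ov_q[i]:
            ov_s[i] = b_seq[i]
            ov_q[i] = b_qual[i]
    return head_s + "".join(ov_s) + tail_s, head_q + "".join(ov_q) + tail_q


# -- anchored insert extraction --------------------------------------------

def _best_hit(frag: np.ndarray, anchor: np.ndarray,
              start: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the best gapless anchor placement at or
    after ``start``; leftmost wins ties."""
    windows = sliding_window_view(frag[start:], len(anchor))
    mism = np.count_nonzero(windows != anchor, axis=1)
    pos = int(np.argmin(mism))
    return start + pos, int(mism[pos])


def extract_insert(fragment: str, layout: ConstructLayout,
                   *, flank_anchor_len: int = 20,
                   max_flank_mismatch: int = 2,
                   ) -> tuple[str | None, str, int]:
    """Locate the insert between genomic flank anchors.

    Returns ``(insert_seq, status, flank_mismatches)`` where status is PASS
    when a 34 nt subsequence sits between both anchors, REJECT_LENGTH when
    the between-anchor length differs from 34, and REJECT_TEMPLATE when an
    anchor cannot be placed within the mismatch budget.
    """
    k = flank_anchor_len
    if k < 1:
        raise ConfigurationError("flank_anchor_len must be >= 1")
    if k > len(fragment):
        raise ConfigurationError(
            f"flank anchor of {k} nt exceeds fragment of {len(fragment)} nt")
    left = to_u8(layout.left_flank(k))
    right = to_u8(layout.right_flank(k))
    frag = to_u8(fragment)
    lpos, lmism = _best_hit(frag, left)
    if lmism > max_flank_mismatch:
        return None, REJECT_TEMPLATE, lmism
    search_from = min(lpos + k, len(fragment) - k)
    rpos, rmism = _best_hit(frag, right, start=search_from)
    if rmism > max_flank_mismatch:
        return None, REJECT_TEMPLATE, lmism + rmism
    insert = fragment[lpos + k:rpos]
    if len(insert) != INSERT_LEN:
        return insert, REJECT_LENGTH, lmism + rmism
    return insert, PASS, lmism + rmism


# -- demultiplexing ---------------------------------------------------------

@dataclass
class DemuxResult:
    status: str
    construct_id: str | None = None
    context: str | None = None
    lesion_base: str | None = None
    barcode: str | None = None
    template_mismatches: int | None = None


def build_barcode_table(layouts: Sequence[ConstructLayout]
                        ) -> dict[str, ConstructLayout]:
    table: dict[str, ConstructLayout] = {}
    for layout in layouts:
        if layout.barcode in table:
            raise ConstructDefinitionError(
                f"duplicate barcode {layout.barcode!r} shared by "
                f"{table[layout.barcode].construct_id!r} and "
                f"{layout.construct_id!r}")
        table[layout.barcode] = layout
    return table


def demux(insert_seq: str,
          barcode_table: Mapping[str, ConstructLayout],
          *, max_template_mismatch: int = 1,
          ) -> DemuxResult:
    """Assign a 34-mer insert to a construct and read off the lesion base.

    The trinucleotide at the barcode offset must match the table exactly;
    the 16-mer is then verified against the construct's lesion-oligo
    template, tolerating ``max_template_mismatch`` mismatches outside the
    lesion position.
    """
    if len(insert_seq) != INSERT_LEN:
        raise ValueError(
            f"demux requires a {INSERT_LEN} nt insert, got {len(insert_seq)}")
    if not barcode_table:
        raise ConfigurationError("barcode table is empty")
    some_layout = next(iter(barcode_table.values()))
    i = some_layout.barcode_offset - 1
    barcode = insert_seq[i:i + 3]
    layout = barcode_table.get(barcode)
    if layout is None:
        return DemuxResult(REJECT_BARCODE, barcode=barcode)
    obs16 = insert_seq[BARCODE_OLIGO_LEN:]
    tmpl = layout.lesion_oligo
    li = layout.lesion_offset - 1
    mism = sum(1 for j in range(LESION_OLIGO_LEN)
               if j != li and obs16[j] != tmpl[j])
    if mism > max_template_mismatch:
        return DemuxResult(REJECT_TEMPLATE, barcode=barcode,
                           template_mismatches=mism)
    return DemuxResult(PASS, construct_id=layout.construct_id,
                       context=layout.context, lesion_base=obs16[li],
                       barcode=barcode, template_mismatches=mism)


# -- whole-sample extraction ------------------------------------------------

def _check_shared_geometry(layouts: Sequence[ConstructLayout]) -> None:
    ref = layouts[0]
    for layout in layouts[1:]:
        if (layout.insertion_site != ref.insertion_site
                or layout.genome_stub != ref.genome_stub
                or layout.barcode_offset != ref.barcode_offset):
            raise ConfigurationError(
                "all constructs in one sample must share the genome stub, "
                "insertion site and barcode offset")


def _batch_merge(seqs1: list[str], quals1: list[str], seqs2: list[str],
                 quals2: list[str], min_overlap: int,
                 max_overlap_mismatch: float
                 ) -> list[tuple[str, str] | None]:
    """Vectorised equivalent of :func:`merge_pair` for uniform-length reads."""
    n = len(seqs1)
    L = len(seqs1[0])
    a = np.frombuffer("".join(seqs1).encode(), dtype=np.uint8).reshape(n, L)
    b_seqs = [revcomp(s) for s in seqs2]
    b = np.frombuffer("".join(b_seqs).encode(), dtype=np.uint8).reshape(n, L)
    best_o = np.zeros(n, dtype=int)
    unresolved = np.ones(n, dtype=bool)
    for o in range(L, min_overlap - 1, -1):
        if not unresolved.any():
            break
        idx = np.flatnonzero(unresolved)
        mism = np.count_nonzero(a[idx, L - o:] != b[idx, :o], axis=1)
        ok = mism <= max_overlap_mismatch * o
        hit = idx[ok]
        best_o[hit] = o
        unresolved[hit] = False
    out: list[tuple[str, str] | None] = []
    for i in range(n):
        o = best_o[i]
        if o == 0:
            out.append(None)
        else:
            out.append(_consensus(seqs1[i], quals1[i], b_seqs[i],
                                  quals2[i][::-1], o))
    return out


def extract_observations(r1_path: str | Path, r2_path: str | Path,
                         layouts: Sequence[ConstructLayout],
                         *, min_overlap: int = 10,
                         max_overlap_mismatch: float = 0.1,
                         flank_anchor_len: int = 20,
                         max_flank_mismatch: int = 2,
                         max_template_mismatch: int = 1,
                         ) -> pd.DataFrame:
    """Run merge -> anchor extraction -> demux over a FASTQ pair.

    Returns one row per input read pair (columns :data:`OBS_COLUMNS`); the
    row's ``status`` records where a rejected pair fell out.  Raises
    ``ValueError`` on malformed input records (empty reads, unpaired files).
    """
    if not layouts:
        raise ConfigurationError("no constructs supplied")
    _check_shared_geometry(layouts)
    table = build_barcode_table(layouts)

    ids: list[str] = []
    s1: list[str] = []
    q1: list[str] = []
    s2: list[str] = []
    q2: list[str] = []
    with open(r1_path) as f1, open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, seq1, qual1), (t2, seq2, qual2) in zip(it1, it2):
            fid = t1.split()[0].split("/")[0]
            fid2 = t2.split()[0].split("/")[0]
            if fid != fid2:
                raise ValueError(
                    f"R1/R2 records out of sync: {fid!r} vs {fid2!r}")
            if not seq1 or not seq2:
                raise ValueError(f"zero-length read in record {fid!r}")
            ids.append(fid)
            s1.append(seq1)
            q1.append(qual1)
            s2.append(seq2)
            q2.append(qual2)
        if next(it1, None) is not None or next(it2, None) is not None:
            raise ValueError("R1 and R2 files have different record counts")

    uniform = (len({len(s) for s in s1} | {len(s) for s in s2}) == 1)
    if uniform and ids:
        merged = _batch_merge(s1, q1, s2, q2, min_overlap,
                              max_overlap_mismatch)
    else:
        merged = [merge_pair(a, b, c, d, min_overlap=min_overlap,
                             max_overlap_mismatch=max_overlap_mismatch)
                  for a, b, c, d in zip(s1, q1, s2, q2)]

    rows: list[InsertObservation] = []
    for fid, m in zip(ids, merged):
        if m is None:
            rows.append(InsertObservation(fid, REJECT_MERGE))
            continue
        fragment, _ = m
        insert, status, flank_mism = extract_insert(
            fragment, layouts[0], flank_anchor_len=flank_anchor_len,
            max_flank_mismatch=max_flank_mismatch)
        if status != PASS:
            rows.append(InsertObservation(fid, status,
                                          flank_mismatches=flank_mism,
                                          insert_seq=insert))
            continue
        d = demux(insert, table,
                  max_template_mismatch=max_template_mismatch)
        rows.append(InsertObservation(
            fid, d.status, construct_id=d.construct_id, context=d.context,
            lesion_base=d.lesion_base, barcode=d.barcode,
            flank_mismatches=flank_mism,
            template_mismatches=d.template_mismatches, insert_seq=insert))

    df = pd.DataFrame([vars(r) for r in rows], columns=OBS_COLUMNS)
    assert len(df) == len(ids), "observation count must equal input pairs"
    return df


def status_counts(observations: pd.DataFrame) -> dict[str, int]:
    """Per-status ledger, including zero counts for absent categories."""
    vc = observations["status"].value_counts()
    return {s: int(vc.get(s, 0)) for s in STATUSES}


def write_observations(observations: pd.DataFrame, path: str | Path) -> None:
    observations.to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: str for c in OBS_COLUMNS
                                              if c not in ("flank_mismatches",
                                                           "template_mismatches")})
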