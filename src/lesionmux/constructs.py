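"""Construct geometry for the site-specific lesion mutagenesis assay.

A construct is a single-stranded circular phage genome (modelled here as a
linear stub) into which a 34-mer insert has been ligated.  The insert is the
ligation product of an 18-mer *barcode oligo* (carrying a trinucleotide
barcode that identifies the construct) and a 16-mer *lesion oligo* (carrying
the interrogated base — adenine in controls, a modified adenine such as
oxo-ϵA in lesion constructs — inside a declared trinucleotide context).

After replication in the host, the base found at the lesion coordinate in
progeny reads encodes the mutagenic outcome; everything downstream of this
module keys off the coordinates defined here.

Coordinates are 1-based inclusive throughout.  The lesion placeholder in
oligo templates and context strings is written ``X`` (e.g. context ``TXG``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConstructDefinitionError
from .seqs import DNA_ALPHABET, is_dna

PLACEHOLDER = "X"
BARCODE_OLIGO_LEN = 18
LESION_OLIGO_LEN = 16
INSERT_LEN = BARCODE_OLIGO_LEN + LESION_OLIGO_LEN  # the 34-mer filter constant

#: Defaults chosen so that the lesion coordinate in the assembled construct is
#: 6262, the centre of the 6244..6280 region of interest used for pileups.
DEFAULT_GENOME_LEN = 7_000
DEFAULT_INSERTION_SITE = 6_237
DEFAULT_ROI = (6_244, 6_280)
DEFAULT_BARCODE_OFFSET = 8  # trinucleotide barcode at 18-mer positions 8-10
DEFAULT_LESION_OFFSET = 8   # interrogated base at 16-mer position 8
_DEFAULT_STUB_SEED = 101

#: Oligo scaffolds: fixed flanking sequence with the variable trinucleotide
#: spliced in at the default offsets.
_BARCODE_SCAFFOLD = ("GGTCTTC", "CTTCGGAC")   # 7 + 3 + 8 = 18 nt
_LESION_SCAFFOLD = ("CGTGGA", "ACGTCTG")      # 6 + 3 + 7 = 16 nt

REFERENCE_BASE = "A"  # the cognate base at the lesion site


@functools.lru_cache(maxsize=8)
def random_genome_stub(length: int = DEFAULT_GENOME_LEN,
                       seed: int = _DEFAULT_STUB_SEED) -> str:
    """Seeded pseudo-random genome stub standing in for the phage genome.

    The real M13mp7(L2) sequence is not packaged; a reproducible random stub
    keeps the assay coordinates (insertion site, region of interest)
    meaningful without any download.
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length)
    return "".join(np.array(list(DNA_ALPHABET))[idx])


@dataclass(frozen=True)
class ConstructLayout:
    """Geometry of one assembled construct.

    Attributes
    ----------
    construct_id:
        Unique label, by convention ``"<identity>_<context>"``.
    genome_stub:
        Linear genome sequence the insert is spliced into.
    insertion_site:
        1-based coordinate of the insert's first base in the assembled
        construct.
    barcode_oligo:
        18 nt, fully resolved (no placeholder); the barcode trinucleotide
        sits at ``barcode_offset .. barcode_offset+2``.
    lesion_oligo:
        16 nt template with ``X`` at ``lesion_offset`` marking the
        interrogated site.
    base_identity:
        What occupies the site in the input genome (``"A"`` for the control,
        a lesion label such as ``"oxoeA"`` otherwise).
    region_of_interest:
        Closed 1-based interval of assembled-construct coordinates over
        which pileups are computed.
    """

    construct_id: str
    genome_stub: str
    insertion_site: int
    barcode_oligo: str
    lesion_oligo: str
    base_identity: str = "A"
    barcode_offset: int = DEFAULT_BARCODE_OFFSET
    lesion_offset: int = DEFAULT_LESION_OFFSET
    region_of_interest: tuple[int, int] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if len(self.barcode_oligo) != BARCODE_OLIGO_LEN:
            raise ConstructDefinitionError(
                f"barcode_oligo must be {BARCODE_OLIGO_LEN} nt, got "
                f"{len(self.barcode_oligo)} ({self.barcode_oligo!r})")
        if len(self.lesion_oligo) != LESION_OLIGO_LEN:
            raise ConstructDefinitionError(
                f"lesion_oligo must be {LESION_OLIGO_LEN} nt, got "
                f"{len(self.lesion_oligo)} ({self.lesion_oligo!r})")
        if not is_dna(self.barcode_oligo):
            raise ConstructDefinitionError(
                f"barcode_oligo contains non-ACGT characters: "
                f"{self.barcode_oligo!r}")
        if not 2 <= self.lesion_offset <= LESION_OLIGO_LEN - 1:
            raise ConstructDefinitionError(
                "lesion_offset must leave at least one flanking base inside "
                f"the 16-mer, got {self.lesion_offset}")
        if self.lesion_oligo[self.lesion_offset - 1] != PLACEHOLDER:
            raise ConstructDefinitionError(
                f"lesion placeholder {PLACEHOLDER!r} absent at position "
                f"{self.lesion_offset} of lesion_oligo {self.lesion_oligo!r}")
        resolved = (self.lesion_oligo[:self.lesion_offset - 1]
                    + self.lesion_oligo[self.lesion_offset:])
        if not is_dna(resolved):
            raise ConstructDefinitionError(
                f"lesion_oligo contains non-ACGT characters outside the "
                f"placeholder: {self.lesion_oligo!r}")
        if not 1 <= self.barcode_offset <= BARCODE_OLIGO_LEN - 2:
            raise ConstructDefinitionError(
                f"barcode_offset {self.barcode_offset} outside the 18-mer")
        if not 1 <= self.insertion_site <= len(self.genome_stub) + 1:
            raise ConstructDefinitionError(
                f"insertion_site {self.insertion_site} outside genome stub "
                f"of length {len(self.genome_stub)}")
        lo, hi = self.region_of_interest
        if lo > hi:
            raise ConstructDefinitionError(
                f"region_of_interest {self.region_of_interest} is empty")
        if not lo <= self.lesion_coordinate <= hi:
            raise ConstructDefinitionError(
                f"lesion coordinate {self.lesion_coordinate} outside the "
                f"region of interest {self.region_of_interest}")

    # -- derived geometry ---------------------------------------------------

    @property
    def barcode(self) -> str:
        """The trinucleotide barcode read from the 18-mer."""
        i = self.barcode_offset - 1
        return self.barcode_oligo[i:i + 3]

    @property
    def context(self) -> str:
        """5'N-X-N3' context read from the lesion oligo, e.g. ``"TXG"``."""
        i = self.lesion_offset - 1
        return (self.lesion_oligo[i - 1] + PLACEHOLDER
                + self.lesion_oligo[i + 1])

    @property
    def insert_template(self) -> str:
        """The 34-mer template (barcode oligo + lesion oligo, 5'->3')."""
        return self.barcode_oligo + self.lesion_oligo

    @property
    def insert_start(self) -> int:
        return self.insertion_site

    @property
    def insert_end(self) -> int:
        return self.insertion_site + INSERT_LEN - 1

    @property
    def lesion_coordinate(self) -> int:
        """1-based coordinate of the interrogated site in the assembly."""
        return self.insertion_site + BARCODE_OLIGO_LEN + self.lesion_offset - 1

    @property
    def lesion_insert_index(self) -> int:
        """0-based index of the lesion position within the 34-mer."""
        return BARCODE_OLIGO_LEN + self.lesion_offset - 1

    @property
    def assembled_length(self) -> int:
        return len(self.genome_stub) + INSERT_LEN

    @property
    def reference_base(self) -> str:
        return REFERENCE_BASE

    def assembled_sequence(self, lesion_base: str = REFERENCE_BASE) -> str:
        """Assembled construct with the placeholder resolved to a base."""
        if lesion_base not in DNA_ALPHABET:
            raise ValueError(f"lesion_base must be one of ACGT: {lesion_base!r}")
        i = self.lesion_offset - 1
        oligo = self.lesion_oligo[:i] + lesion_base + self.lesion_oligo[i + 1:]
        cut = self.insertion_site - 1
        return (self.genome_stub[:cut] + self.barcode_oligo + oligo
                + self.genome_stub[cut:])

    def left_flank(self, length: int) -> str:
        """Genomic sequence immediately 5' of the insert."""
        cut = self.insertion_site - 1
        if length > cut:
            raise ConstructDefinitionError(
                f"left flank of {length} nt exceeds available genome")
        return self.genome_stub[cut - length:cut]

    def right_flank(self, length: int) -> str:
        """Genomic sequence immediately 3' of the insert."""
        cut = self.insertion_site - 1
        if cut + length > len(self.genome_stub):
            raise ConstructDefinitionError(
                f"right flank of {length} nt exceeds available genome")
        return self.genome_stub[cut:cut + length]


def build_construct(genome_stub: str,
                    barcode_oligo: str,
                    lesion_oligo: str,
                    insertion_site: int,
                    *,
                    construct_id: str | None = None,
                    base_identity: str = "A",
                    barcode_offset: int = DEFAULT_BARCODE_OFFSET,
                    lesion_offset: int = DEFAULT_LESION_OFFSET,
                    region_of_interest: tuple[int, int] = DEFAULT_ROI,
                    ) -> ConstructLayout:
    """Assemble a :class:`ConstructLayout`, validating the oligo geometry.

    Raises :class:`ConstructDefinitionError` when an oligo has the wrong
    length, the lesion placeholder is absent, or the coordinates are
    inconsistent.
    """
    layout = ConstructLayout(
        construct_id=construct_id or "construct",
        genome_stub=genome_stub,
        insertion_site=insertion_site,
        barcode_oligo=barcode_oligo,
        lesion_oligo=lesion_oligo,
        base_identity=base_identity,
        barcode_offset=barcode_offset,
        lesion_offset=lesion_offset,
        region_of_interest=region_of_interest,
    )
    if construct_id is None:
        layout = replace(layout,
                         construct_id=f"{base_identity}_{layout.context}")
    return layout


def trinucleotide_contexts() -> list[str]:
    """All 16 NXN contexts in lexicographic order of the flanking bases."""
    return [a + PLACEHOLDER + b
            for a, b in product(DNA_ALPHABET, DNA_ALPHABET)]


def default_barcodes(n: int) -> list[str]:
    """First ``n`` trinucleotides in lexicographic order (AAA, AAC, ...)."""
    if n > 64:
        raise ConstructDefinitionError(
            f"only 64 trinucleotide barcodes exist, {n} requested")
    return ["".join(t) for t in product(DNA_ALPHABET, repeat=3)][:n]


def make_barcode_oligo(barcode: str,
                       barcode_offset: int = DEFAULT_BARCODE_OFFSET) -> str:
    if len(barcode) != 3 or not is_dna(barcode):
        raise ConstructDefinitionError(f"barcode must be a trinucleotide over "
                                       f"ACGT, got {barcode!r}")
    left, right = _BARCODE_SCAFFOLD
    if barcode_offset != DEFAULT_BARCODE_OFFSET:
        raise ConstructDefinitionError(
            "the packaged scaffold places the barcode at positions 8-10; "
            "supply a full barcode_oligo for other offsets")
    return left + barcode + right


def make_lesion_oligo(context: str,
                      lesion_offset: int = DEFAULT_LESION_OFFSET) -> str:
    _validate_context(context)
    left, right = _LESION_SCAFFOLD
    if lesion_offset != DEFAULT_LESION_OFFSET:
        raise ConstructDefinitionError(
            "the packaged scaffold places the lesion at position 8; supply a "
            "full lesion_oligo for other offsets")
    return left + context + right


def _validate_context(context: str) -> None:
    if (len(context) != 3 or context[1] != PLACEHOLDER
            or context[0] not in DNA_ALPHABET
            or context[2] not in DNA_ALPHABET):
        raise ConstructDefinitionError(
            f"context must be of the form NXN over ACGT, got {context!r}")


def enumerate_pool(contexts: Sequence[str],
                   base_identities: Sequence[str],
                   *,
                   genome_stub: str | None = None,
                   insertion_site: int = DEFAULT_INSERTION_SITE,
                   barcodes: Sequence[str] | None = None,
                   region_of_interest: tuple[int, int] = DEFAULT_ROI,
                   ) -> list[ConstructLayout]:
    """Enumerate the construct pool: one construct per (identity, context).

    Each construct receives a distinct trinucleotide barcode; the default
    assignment walks trinucleotides in lexicographic order (barcode sequences
    are a bookkeeping choice, not data).  Duplicate contexts or duplicate
    barcode assignments raise :class:`ConstructDefinitionError`.
    """
    if not contexts:
        raise ConstructDefinitionError("contexts must be non-empty")
    if not base_identities:
        raise ConstructDefinitionError("base_identities must be non-empty")
    for c in contexts:
        _validate_context(c)
    if len(set(contexts)) != len(contexts):
        raise ConstructDefinitionError("duplicate context in pool definition")
    if len(set(base_identities)) != len(base_identities):
        raise ConstructDefinitionError("duplicate base identity in pool")

    n = len(contexts) * len(base_identities)
    if barcodes is None:
        barcodes = default_barcodes(n)
    if len(barcodes) != n:
        raise ConstructDefinitionError(
            f"{n} barcodes needed for {len(base_identities)} identities x "
            f"{len(contexts)} contexts, got {len(barcodes)}")
    if len(set(barcodes)) != len(barcodes):
        raise ConstructDefinitionError("duplicate barcode assignment")

    stub = genome_stub if genome_stub is not None else random_genome_stub()
    layouts = []
    k = 0
    for identity in base_identities:
        for context in contexts:
            layouts.append(build_construct(
                stub,
                make_barcode_oligo(barcodes[k]),
                make_lesion_oligo(context),
                insertion_site,
                construct_id=f"{identity}_{context}",
                base_identity=identity,
                region_of_interest=region_of_interest,
            ))
            k += 1
    return layouts


# -- construct sheet I/O ----------------------------------------------------

SHEET_COLUMNS = ["construct_id", "base_identity", "context", "barcode",
                 "barcode_oligo", "lesion_oligo", "insertion_site",
                 "barcode_offset", "lesion_offset", "roi_start", "roi_end"]


def write_construct_sheet(layouts: Iterable[ConstructLayout],
                          path: str | Path) -> None:
    """Write constructs as a tab-separated sheet (genome stub not included;
    it is regenerated from its seed or supplied on load)."""
    rows = [{
        "construct_id": l.construct_id,
        "base_identity": l.base_identity,
        "context": l.context,
        "barcode": l.barcode,
        "barcode_oligo": l.barcode_oligo,
        "lesion_oligo": l.lesion_oligo,
        "insertion_site": l.insertion_site,
        "barcode_offset": l.barcode_offset,
        "lesion_offset": l.lesion_offset,
        "roi_start": l.region_of_interest[0],
        "roi_end": l.region_of_interest[1],
    } for l in layouts]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def read_construct_sheet(path: str | Path,
                         genome_stub: str | None = None,
                         ) -> list[ConstructLayout]:
    """Load constructs from a sheet written by :func:`write_construct_sheet`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode_oligo": str,
                                            "lesion_oligo": str})
    stub = genome_stub if genome_stub is not None else random_genome_stub()
    layouts = []
    for row in df.itertuples(index=False):
        layouts.append(ConstructLayout(
            construct_id=row.construct_id,
            genome_stub=stub,
            insertion_site=int(row.insertion_site),
            barcode_oligo=row.barcode_oligo,
            lesion_oligo=row.lesion_oligo,
            base_identity=row.base_identity,
            barcode_offset=int(row.barcode_offset),
            lesion_offset=int(row.lesion_offset),
            region_of_interest=(int(row.roi_start), int(row.roi_end)),
        ))
    return layouts
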