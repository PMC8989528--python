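"""Progeny-read simulator: the in-silico stand-in for phage replication.

The wet-lab experiment electroporates single-stranded lesion-bearing genomes
into the host, amplifies progeny phage, PCR-amplifies a window around the
insert and sequences it paired-end.  This module replaces all of that with a
seeded generative model:

* each fragment is drawn from a molar mix of constructs,
* its lesion-site base is drawn from the construct's outcome profile
  (the post-replication miscoding distribution),
* with some probability the fragment carries a truncated (28-33 nt) insert,
  modelling failed ligation products that the 34-mer filter must reject,
* i.i.d. substitution sequencing errors are added to both reads.

Outputs are ordinary Phred+33 FASTQ pairs plus a truth table so every
downstream stage can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constructs import ConstructLayout
from .errors import ConfigurationError
from .seqs import DNA_ALPHABET, revcomp

__all__ = [
    "OutcomeProfile", "PRESETS", "get_preset", "SimulationConfig",
    "SimulatedRun", "simulate_reads", "read_truth_table",
]

_TRUNC_MIN, _TRUNC_MAX = 28, 33  # malformed-insert lengths (inclusive)


@dataclass(frozen=True)
class OutcomeProfile:
    """Probability of observing each canonical base at the lesion site.

    This is the generative ground truth that the spectrum module estimates:
    the relative proportion of A, C, G and T replacing the interrogated base
    in progeny reads.
    """

    p_a: float
    p_c: float
    p_g: float
    p_t: float
    label: str = ""

    def __post_init__(self) -> None:
        p = self.probs
        if np.any(p < 0):
            raise ValueError(f"outcome probabilities must be >= 0: {p}")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError(
                f"outcome probabilities must sum to 1 (got {p.sum()!r}) "
                f"for profile {self.label!r}")

    @property
    def probs(self) -> np.ndarray:
        """Probabilities in A, C, G, T order."""
        return np.array([self.p_a, self.p_c, self.p_g, self.p_t])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DNA_ALPHABET, self.probs))


#: Preset outcome profiles.
#:
#: * ``control_A`` — unmodified adenine control; 0.2% total miscoding models
#:   the assay noise floor (replication infidelity + residual artefacts).
#: * ``oxoeA_TXG`` — oxo-ϵA in the TXG context: 97% mutagenic with 95% of
#:   mutations being A→T transversions; the residual C/G split is symmetric.
#: * ``oxoeA_pool_default`` — oxo-ϵA in the 13 contexts without a 5'G-C/G/T
#:   signature: >99% mutagenic, almost all A→T.
#: * ``oxoeA_pool_GXC_GXG_GXT`` — oxo-ϵA in GXC/GXG/GXT where ~2% of reads
#:   carry C at the lesion site (oxo-ϵA:G pairing leaking through).
PRESETS: dict[str, OutcomeProfile] = {
    "control_A": OutcomeProfile(
        0.998, 0.002 / 3, 0.002 / 3, 0.002 / 3, label="control_A"),
    "oxoeA_TXG": OutcomeProfile(
        0.03, 0.02425, 0.02425, 0.9215, label="oxoeA_TXG"),
    "oxoeA_pool_default": OutcomeProfile(
        0.005, 0.006, 0.006, 0.983, label="oxoeA_pool_default"),
    "oxoeA_pool_GXC_GXG_GXT": OutcomeProfile(
        0.005, 0.02, 0.003, 0.972, label="oxoeA_pool_GXC_GXG_GXT"),
}


def get_preset(name: str) -> OutcomeProfile:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown outcome preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None


@dataclass
class SimulationConfig:
    """Parameters of one simulated sequencing sample.

    ``genome_mix`` lists (construct, outcome profile, molar fraction)
    triples; fractions must sum to 1.  ``fragment_length`` is the length of
    the PCR-fragment window centred on the insert; it must not exceed
    2 x read_length minus the merge overlap so that read pairs overlap.
    """

    genome_mix: Sequence[tuple[ConstructLayout, OutcomeProfile, float]]
    n_read_pairs: int
    read_length: int = 150
    substitution_error_rate: float = 0.001
    malformed_insert_fraction: float = 0.02
    quality_phred: int = 30
    fragment_length: int = 240
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.genome_mix:
            raise ConfigurationError("genome_mix must be non-empty")
        fracs = np.array([f for _, _, f in self.genome_mix], dtype=float)
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"molar fractions must be >= 0 and sum to 1, got {fracs}")
        if self.n_read_pairs <= 0:
            raise ConfigurationError("n_read_pairs must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        for name in ("substitution_error_rate", "malformed_insert_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 2 <= self.quality_phred <= 60:
            raise ConfigurationError("quality_phred must be in [2, 60]")


@dataclass
class SimulatedRun:
    """Paths and bookkeeping for one simulated sample."""

    r1_path: Path
    r2_path: Path
    truth_path: Path
    n_read_pairs: int
    amplicon_window: tuple[int, int]


def default_amplicon_window(layout: ConstructLayout,
                            fragment_length: int) -> tuple[int, int]:
    """Fragment window centred on the insert, in assembled coordinates."""
    flank = (fragment_length - (layout.insert_end - layout.insert_start + 1))
    left = flank // 2
    start = layout.insert_start - left
    end = start + fragment_length - 1
    return (start, end)


def _check_window(layout: ConstructLayout, window: tuple[int, int],
                  read_length: int) -> None:
    start, end = window
    length = end - start + 1
    if length < read_length:
        raise ConfigurationError(
            f"amplicon window of {length} nt is shorter than the read "
            f"length {read_length}")
    if start < 1 or end > layout.assembled_length:
        raise ConfigurationError(
            f"amplicon window {window} falls outside the assembled "
            f"construct (length {layout.assembled_length})")
    if not (start < layout.insert_start and end > layout.insert_end):
        raise ConfigurationError(
            f"amplicon window {window} must contain the insert "
            f"({layout.insert_start}..{layout.insert_end}) with flanks")


def simulate_reads(config: SimulationConfig,
                   out_dir: str | Path,
                   prefix: str = "sim",
                   amplicon_window: tuple[int, int] | None = None,
                   ) -> SimulatedRun:
    """Simulate paired-end progeny reads for one sample.

    Writes ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq`` (Phred+33) and
    ``<prefix>_truth.tsv`` (fragment_id, construct_id, lesion_base,
    malformed) to ``out_dir``.  Identical configs produce byte-identical
    output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layouts = [l for l, _, _ in config.genome_mix]
    window = amplicon_window or default_amplicon_window(
        layouts[0], config.fragment_length)
    for layout in layouts:
        _check_window(layout, window, config.read_length)

    rng = np.random.default_rng(config.seed)
    n = config.n_read_pairs
    L = config.read_length
    win_start, win_end = window

    # Per-construct fragment templates split at the insert, so a fragment is
    # rebuilt as pre + (possibly truncated) resolved insert + post.
    pres, posts, insert_tmpls, lesion_idx = [], [], [], []
    for layout in layouts:
        assembled = layout.assembled_sequence("A")  # placeholder filled below
        frag = assembled[win_start - 1:win_end]
        ins_off = layout.insert_start - win_start
        pres.append(frag[:ins_off])
        posts.append(frag[ins_off + 34:])
        tmpl = layout.insert_template  # still contains the X placeholder
        insert_tmpls.append(tmpl)
        lesion_idx.append(layout.lesion_insert_index)

    fracs = np.array([f for _, _, f in config.genome_mix], dtype=float)
    fracs = fracs / fracs.sum()
    cons_idx = rng.choice(len(layouts), size=n, p=fracs)

    # Inverse-CDF draw of the lesion-site base per fragment.
    prob_rows = np.stack([p.probs for _, p, _ in config.genome_mix])
    cdfs = np.cumsum(prob_rows, axis=1)
    u = rng.random(n)
    base_idx = (u[:, None] > cdfs[cons_idx]).sum(axis=1)

    malformed = rng.random(n) < config.malformed_insert_fraction
    trunc_len = rng.integers(_TRUNC_MIN, _TRUNC_MAX + 1, size=n)
    err_counts = rng.binomial(L, config.substitution_error_rate, size=(n, 2))

    qual_line = chr(config.quality_phred + 33) * L
    alphabet = DNA_ALPHABET
    r1_path = out_dir / f"{prefix}_R1.fastq"
    r2_path = out_dir / f"{prefix}_R2.fastq"
    truth_path = out_dir / f"{prefix}_truth.tsv"

    truth_cids = np.empty(n, dtype=object)
    truth_bases = np.empty(n, dtype=object)

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i in range(n):
            c = cons_idx[i]
            base = alphabet[base_idx[i]]
            li = lesion_idx[c]
            tmpl = insert_tmpls[c]
            insert = tmpl[:li] + base + tmpl[li + 1:]
            if malformed[i]:
                insert = insert[:trunc_len[i]]
            frag = pres[c] + insert + posts[c]
            r1 = frag[:L]
            r2 = revcomp(frag[-L:])
            if err_counts[i, 0]:
                r1 = _add_errors(r1, err_counts[i, 0], rng, alphabet)
            if err_counts[i, 1]:
                r2 = _add_errors(r2, err_counts[i, 1], rng, alphabet)
            fid = f"frag{i:07d}"
            f1.write(f"@{fid}/1\n{r1}\n+\n{qual_line}\n")
            f2.write(f"@{fid}/2\n{r2}\n+\n{qual_line}\n")
            truth_cids[i] = layouts[c].construct_id
            truth_bases[i] = base

    truth = pd.DataFrame({
        "fragment_id": [f"frag{i:07d}" for i in range(n)],
        "construct_id": truth_cids,
        "lesion_base": truth_bases,
        "malformed": malformed.astype(int),
    })
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedRun(r1_path, r2_path, truth_path, n, window)


def _add_errors(read: str, k: int, rng: np.random.Generator,
                alphabet: str) -> str:
    """Substitute ``k`` distinct positions with one of the 3 other bases."""
    pos = rng.choice(len(read), size=k, replace=False)
    chars = list(read)
    for p in pos:
        shift = rng.integers(1, 4)
        chars[p] = alphabet[(alphabet.index(chars[p]) + shift) % 4]
    return "".join(chars)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"fragment_id": str, "construct_id": str,
                              "lesion_base": str, "malformed": int})
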