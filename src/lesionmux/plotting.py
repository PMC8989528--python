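"""Static composition bar charts of lesion-site spectra.

Matplotlib is imported lazily; install the ``plot`` extra to use this
module.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .seqs import DNA_ALPHABET
from .spectrum import SpectrumResult


def composition_barplot(spectra: Sequence[SpectrumResult],
                        out_path: str | Path,
                        title: str = "Lesion-site base composition") -> None:
    """Grouped bar chart: per group, the fraction of each base observed at
    the lesion site (all-reads scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    labels = [s.context or s.construct_id or "?" for s in spectra]
    x = np.arange(len(spectra))
    width = 0.2
    fig, ax = plt.subplots(figsize=(max(6, len(spectra)), 4))
    for i, base in enumerate(DNA_ALPHABET):
        vals = [s.fractions.get(base, 0.0) for s in spectra]
        ax.bar(x + (i - 1.5) * width, vals, width, label=base)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90)
    ax.set_ylabel("fraction of reads at lesion site")
    ax.set_title(title)
    ax.legend(title="base")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
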