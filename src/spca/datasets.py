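"""Packaged example data.

The PDZ domain family is the classic worked example for this analysis: a
~90-100 residue protein-interaction module (six beta strands, two alpha
helices) whose 186 crystal structures, aligned over 96 columns after gap
reduction, yield a well-characterised set of strongly coupled position
pairs. The pair list ships with the package so the segment construction can
be exercised without any structure downloads.
"""

from __future__ import annotations

from importlib import resources

#: columns of the reduced PDZ family alignment the pair list refers to
PDZ_ALIGNMENT_LENGTH = 96


def pdz_pairs() -> list[tuple[int, int, float]]:
    """The PDZ high-correlation pair list (r > 0.60), 0-based indices.

    Both orientations of each pair are present (symmetric listing); use
    together with :data:`PDZ_ALIGNMENT_LENGTH`.
    """
    text = resources.files("spca.data").joinpath("pdz_pairs.tsv").read_text()
    out: list[tuple[int, int, float]] = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        i, j, r = line.split("\t")
        out.append((int(i) - 1, int(j) - 1, float(r)))
    return out
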