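"""Screening single-copy ortholog alignments for strain-typing markers.

A useful PCR-typeable marker combines enough inter-species variation to
separate the species (inter-species SNP density within a closed 20-40%
band), enough intra-species variation to separate conspecific strains
(strictly above 1%), and a fully conserved flanking window near each end of
the alignment for consensus primer design. Densities are computed on
nucleotide alignments, since primers are nucleotide-level; columns
containing any gap are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .phylo import Msa


@dataclass
class MarkerStats:
    family_id: str
    inter_density_pct: float
    intra_density_pct: float | None  # None when no species has >= 2 strains
    flank_ok: bool
    passes: bool


def _ungapped_columns(msa: Msa) -> list[int]:
    return [
        j for j in range(msa.n_cols) if all(r[j] != "-" for r in msa.rows)
    ]


def snp_densities(
    msa: Msa, species_map: dict[str, str], mode: str = "consensus"
) -> tuple[float, float | None]:
    """(inter_density_pct, intra_density_pct) of an alignment.

    inter: % of ungapped columns where the per-species consensus differs
    between species (or, in 'pairwise' mode, where any two sequences of
    different species differ). intra: % of ungapped columns polymorphic
    among conspecific strains of at least one species; None when no species
    contributes >= 2 strains.
    """
    species = sorted({species_map[n] for n in msa.names})
    if len(species) < 2:
        raise ValueError("need at least two species")
    rows_of = {
        sp: [r for n, r in zip(msa.names, msa.rows) if species_map[n] == sp]
        for sp in species
    }
    cols = _ungapped_columns(msa)
    if not cols:
        return 0.0, None
    multi = [sp for sp in species if len(rows_of[sp]) >= 2]

    inter = 0
    intra = 0
    for j in cols:
        if mode == "consensus":
            consensi = []
            for sp in species:
                counts = Counter(r[j] for r in rows_of[sp])
                # tie-break: highest count, then lexicographically smallest
                best_n = max(counts.values())
                consensi.append(min(c for c, k in counts.items() if k == best_n))
            if len(set(consensi)) > 1:
                inter += 1
        elif mode == "pairwise":
            chars_by_sp = {sp: {r[j] for r in rows_of[sp]} for sp in species}
            if any(
                chars_by_sp[a] - chars_by_sp[b] or chars_by_sp[b] - chars_by_sp[a]
                for a in species
                for b in species
                if a < b
            ):
                inter += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if multi and any(len({r[j] for r in rows_of[sp]}) > 1 for sp in multi):
            intra += 1

    inter_pct = 100.0 * inter / len(cols)
    intra_pct = 100.0 * intra / len(cols) if multi else None
    return inter_pct, intra_pct


def flank_conservation(
    msa: Msa, window_len: int = 20, max_mismatch: int = 0, search_span: int = 200
) -> bool:
    """True iff a gap-free window of window_len with at most max_mismatch
    polymorphic columns exists within search_span of both alignment ends."""
    n = msa.n_cols
    if n <= 2 * window_len:
        return False

    def conserved(j: int) -> bool:
        chars = {r[j] for r in msa.rows}
        return "-" not in chars and len(chars) == 1

    flags = [conserved(j) for j in range(n)]

    def has_window(start: int, stop: int) -> bool:
        for s in range(start, max(stop - window_len + 1, start)):
            window = flags[s : s + window_len]
            if len(window) == window_len and sum(not f for f in window) <= max_mismatch:
                return True
        return False

    left = has_window(0, min(search_span, n))
    right = has_window(max(n - search_span, 0), n)
    return left and right


def screen_markers(
    families: dict[str, Msa],
    species_map: dict[str, str],
    inter_range: tuple[float, float] = (20.0, 40.0),
    intra_min: float = 1.0,
    window_len: int = 20,
    search_span: int = 200,
) -> list[MarkerStats]:
    """Rank candidate markers: pass iff inter density lies in the closed
    range, intra density strictly exceeds the minimum, and both flanks hold
    a conserved primer window. Ranked by intra density, descending."""
    out = []
    for fam_id in sorted(families):
        msa = families[fam_id]
        inter, intra = snp_densities(msa, species_map)
        flank = flank_conservation(msa, window_len=window_len, search_span=search_span)
        passes = (
            inter_range[0] <= inter <= inter_range[1]
            and intra is not None
            and intra > intra_min
            and flank
        )
        out.append(MarkerStats(fam_id, inter, intra, flank, passes))
    out.sort(key=lambda m: (-(m.intra_density_pct or -1.0), m.family_id))
    return out


def write_marker_report(stats: Sequence[MarkerStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tinter_pct\tintra_pct\tflank_ok\tpass\trank\n")
        for rank, m in enumerate(stats, start=1):
            intra = "" if m.intra_density_pct is None else f"{m.intra_density_pct:.2f}"
            fh.write(
                f"{m.family_id}\t{m.inter_density_pct:.2f}\t{intra}"
                f"\t{int(m.flank_ok)}\t{int(m.passes)}\t{rank}\n"
            )
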