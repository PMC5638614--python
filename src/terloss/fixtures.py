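"""Packaged worked examples and scenario fixture files.

The centrepiece is the time-lapse counting schematic used to define the
initial-event statistic: nine countable divisions of which two (numbers 2
and 7) are initial events; the retaining branch of event 2 keeps producing
focus-less daughters (inherited divisions, not counted), event 7 has no
observable progeny.  The classifier must recover 2 initial events out of 9
counted divisions with 100% transmission among observable events.

:func:`make_fixtures` also emits the scenario map configs and a small
synthetic FASTA with planted KOPS/Chi motifs and a GC-skew switch, with the
expected hits alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .genome import MotifHit, scan_motif
from .lineage import LineageTable
from .scenarios import SCENARIO_NAMES, get_scenario

KOPS = "GGGNAGGG"
CHI = "GCTGGTGG"


def fig2e_table() -> LineageTable:
    """The counting-schematic lineage: 2 initial events over 9 divisions.

    Division ids 1..9 are the countable ones (2 and 7 are the initial
    events); X1/X2 are the inherited-loss divisions on the retaining branch
    of event 2.  The retaining daughter of event 7 is censored, so that
    event is not observable for transmission.
    """
    rows = [
        # division_id, frame, mother, d1, d2, d1_focus, d2_focus
        ("1", 1, "R", "A", "B", True, True),
        ("2", 2, "A", "C", "D", False, True),   # initial event; C arrests
        ("X1", 3, "D", "E", "F", False, True),  # inherited
        ("X2", 4, "F", "G", "H", False, True),  # inherited
        ("3", 2, "B", "I", "J", True, True),
        ("4", 3, "I", "K", "L", True, True),
        ("5", 3, "J", "M", "N", True, True),
        ("6", 4, "K", "O", "P", True, True),
        ("7", 4, "L", "Q", "S", False, True),   # initial event; no progeny seen
        ("8", 4, "M", "T", "U", True, True),
        ("9", 4, "N", "V", "W", True, True),
    ]
    divisions = pd.DataFrame(rows, columns=[
        "division_id", "frame", "mother", "daughter1", "daughter2",
        "daughter1_focus", "daughter2_focus",
    ])
    return LineageTable(divisions=divisions)


def _scrub(seq: list[str], motifs: list[str], rng: np.random.Generator) -> None:
    """Mutate accidental motif matches (either strand) until none remain.

    The mutated base is the first non-wildcard position of the pattern as it
    reads on the matched strand (mutating an N position would not break the
    match), replaced by a base the IUPAC code does not allow.
    """
    from .genome import _IUPAC, reverse_complement

    for _ in range(200):
        dirty = False
        for motif in motifs:
            for h in scan_motif("".join(seq), motif):
                pat = motif if h.strand == "+" else reverse_complement(motif)
                j = next(k for k, c in enumerate(pat) if c != "N")
                allowed = set(_IUPAC[pat[j]])
                choices = [c for c in "ACGT" if c not in allowed]
                seq[h.position + j] = choices[rng.integers(len(choices))]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub background sequence of motif matches")


def planted_motif_sequence(
    length: int = 20_000, seed: int = 2024
) -> tuple[str, list[MotifHit], list[MotifHit]]:
    """(sequence, kops_hits, chi_hits) for a toy circular genome.

    The sequence origin plays the role of oriC; '+'-oriented motifs are
    planted on the first half and '-'-oriented on the second half so both
    motif orientation and GC skew converge at the midpoint.  The G-rich
    first half / C-rich second half gives the cumulative GC skew its
    maximum there.
    """
    rng = np.random.default_rng(seed)
    half = length // 2
    # biased background: G over C on the first half, C over G on the second
    probs_first = [0.24, 0.16, 0.36, 0.24]  # A C G T
    probs_second = [0.24, 0.36, 0.16, 0.24]
    letters = np.array(list("ACGT"))
    seq = list(
        "".join(letters[rng.choice(4, size=half, p=probs_first)])
        + "".join(letters[rng.choice(4, size=length - half, p=probs_second)])
    )
    _scrub(seq, [KOPS, CHI], rng)

    kops_fwd = "GGGTAGGG"
    kops_rev = "CCCTACCC"  # reverse complement of GGGTAGGG
    chi_fwd = CHI
    chi_rev = "CCACCAGC"
    plan = []
    for pos in range(1_000, half - 1_000, 2_500):
        plan.append((pos, kops_fwd))
    for pos in range(half + 1_000, length - 1_000, 2_500):
        plan.append((pos, kops_rev))
    for pos in range(2_200, half - 1_000, 5_000):
        plan.append((pos, chi_fwd))
    for pos in range(half + 2_200, length - 1_000, 5_000):
        plan.append((pos, chi_rev))
    for pos, motif in plan:
        seq[pos : pos + len(motif)] = list(motif)
    s = "".join(seq)
    kops_hits = scan_motif(s, KOPS)
    chi_hits = scan_motif(s, CHI)
    expected_kops = sorted(p for p, m in plan if m in (kops_fwd, kops_rev))
    if sorted(h.position for h in kops_hits) != expected_kops:
        raise RuntimeError("planting produced unexpected KOPS matches")
    expected_chi = sorted(p for p, m in plan if m in (chi_fwd, chi_rev))
    if sorted(h.position for h in chi_hits) != expected_chi:
        raise RuntimeError("planting produced unexpected Chi matches")
    return s, kops_hits, chi_hits


def _write_hits(hits: list[MotifHit], path: Path) -> None:
    pd.DataFrame(
        [(h.position, h.strand, h.motif) for h in hits],
        columns=["position", "strand", "motif"],
    ).to_csv(path, sep="\t", index=False)


def make_fixtures(target_dir) -> dict[str, Path]:
    """Write all packaged fixtures into ``target_dir``; returns the paths."""
    out = Path(target_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = fig2e_table()
    paths["lineage_divisions"] = out / "counting_example_divisions.tsv"
    paths["lineage_cells"] = out / "counting_example_cells.tsv"
    tio.write_lineage_tsv(table, paths["lineage_divisions"], paths["lineage_cells"])

    for name in SCENARIO_NAMES:
        sc = get_scenario(name)
        p = out / f"map_{name}.yaml"
        tio.write_map_yaml(sc.chrom, p)
        paths[f"map_{name}"] = p

    seq, kops_hits, chi_hits = planted_motif_sequence()
    paths["fasta"] = out / "planted_motifs.fasta"
    tio.write_fasta(
        paths["fasta"], "synthetic_toy_genome", seq,
        description="synthetic circular toy genome with planted KOPS/Chi motifs",
    )
    paths["kops_hits"] = out / "planted_motifs_kops.tsv"
    paths["chi_hits"] = out / "planted_motifs_chi.tsv"
    _write_hits(kops_hits, paths["kops_hits"])
    _write_hits(chi_hits, paths["chi_hits"])
    return paths
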