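"""Drosophila-like block-copolymer genomes and the nuclear lamina shell.

The fly genome is modeled as four bead-spring chains — Chr2, Chr3, Chr4 and
ChrX at 60.5, 68.8, 4.5 and 42.4 Mbp — with 5 kbp per bead (12100, 13760,
900 and 8480 beads; 35240 in total).  Each chain is a non-periodic block
copolymer of euchromatin (EU) and heterochromatin (HET) segments, and the
euchromatic blocks may carry lamina-associated-domain (LAD) flags that make
them stick to an immobile shell of lamin beads lining the confinement
sphere.

Real EU/HET and LAD interval tracks can be supplied as BED-like TSV tables
(chrom, start_bp, end_bp, label; 0-based half-open).  When none are given,
a synthetic alternating-block generator stands in: block lengths are drawn
from exponential distributions with a configurable HET genome fraction, a
coarse statistical mimic of the pericentromeric-plus-interspersed layout of
real annotation tracks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model_core import EU, HET, LAMIN, GenomeSpec, PolymerSystem

__all__ = [
    "DROSOPHILA_BP_SIZES",
    "build_drosophila_genome",
    "synth_interval_table",
    "build_lamina_shell",
    "add_lamina_shell",
]

DROSOPHILA_BP_SIZES = {
    "Chr2": 60_500_000,
    "Chr3": 68_800_000,
    "Chr4": 4_500_000,
    "ChrX": 42_400_000,
}


def _load_intervals(intervals):
    if intervals is None:
        return None
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
    else:
        df = pd.read_csv(
            intervals, sep="\t", header=None, comment="#",
            names=["chrom", "start_bp", "end_bp", "label"],
            usecols=[0, 1, 2, 3],
        )
    df.columns = ["chrom", "start_bp", "end_bp", "label"]
    return df


def synth_interval_table(bp_sizes=None, het_fraction=0.3,
                         mean_eu_block_bp=500_000, lad_fraction=0.4,
                         mean_lad_block_bp=250_000, seed=0):
    """Synthetic EU/HET and LAD interval tables (stand-in annotation).

    Alternating EU/HET blocks with exponential lengths: the mean HET block
    is sized so heterochromatin covers ``het_fraction`` of each chromosome.
    LAD blocks alternate similarly along the chromosome and are later
    restricted to euchromatin by the genome builder.  Returns
    (eu_het_table, lad_table) as BED-like DataFrames.
    """
    bp_sizes = bp_sizes or DROSOPHILA_BP_SIZES
    rng = np.random.default_rng(seed)
    mean_het = mean_eu_block_bp * het_fraction / max(1e-9, 1.0 - het_fraction)
    eh_rows, lad_rows = [], []
    for chrom, size in bp_sizes.items():
        pos = 0
        state = EU if rng.random() > het_fraction else HET
        while pos < size:
            mean = mean_eu_block_bp if state == EU else mean_het
            length = max(5000, int(rng.exponential(mean)))
            end = min(size, pos + length)
            eh_rows.append((chrom, pos, end, "EU" if state == EU else "HET"))
            pos = end
            state = HET if state == EU else EU
        pos = 0
        lad_on = rng.random() < lad_fraction
        while pos < size:
            if lad_on:
                mean = mean_lad_block_bp
            else:
                mean = mean_lad_block_bp * (1 - lad_fraction) / max(
                    1e-9, lad_fraction
                )
            length = max(5000, int(rng.exponential(mean)))
            end = min(size, pos + length)
            if lad_on:
                lad_rows.append((chrom, pos, end, "LAD"))
            pos = end
            lad_on = not lad_on
    cols = ["chrom", "start_bp", "end_bp", "label"]
    return (pd.DataFrame(eh_rows, columns=cols),
            pd.DataFrame(lad_rows, columns=cols))


def _per_bead_coverage(df, chrom, n_beads, bp_per_bead, labels):
    """bp of each label overlapping each bead of one chromosome."""
    cov = {lab: np.zeros(n_beads) for lab in labels}
    sub = df[df["chrom"] == chrom]
    size = n_beads * bp_per_bead
    for _, row in sub.iterrows():
        lo, hi = int(row["start_bp"]), int(row["end_bp"])
        if lo < 0 or hi > size + bp_per_bead - 1 or lo >= hi:
            raise ValueError(
                f"interval {chrom}:{lo}-{hi} outside chromosome bounds"
            )
        lab = row["label"]
        if lab not in cov:
            continue
        b0 = lo // bp_per_bead
        b1 = min(n_beads - 1, (hi - 1) // bp_per_bead)
        for b in range(b0, b1 + 1):
            bead_lo = b * bp_per_bead
            bead_hi = bead_lo + bp_per_bead
            cov[lab][b] += min(hi, bead_hi) - max(lo, bead_lo)
    return cov


def build_drosophila_genome(bp_sizes=None, eu_het_intervals=None,
                            lad_intervals=None, bp_per_bead=5000,
                            seed=0) -> GenomeSpec:
    """Bead-resolution block-copolymer spec of the four fly chromosomes.

    Bead counts are round(bp/bp_per_bead); each bead takes the chromatin
    class covering the majority of its basepairs (EU by default), and LAD
    flags are kept only on euchromatic beads (LAD annotation exists only
    for euchromatin).  Without interval tables the synthetic generator
    provides the annotation.
    """
    bp_sizes = bp_sizes or DROSOPHILA_BP_SIZES
    eh = _load_intervals(eu_het_intervals)
    lad = _load_intervals(lad_intervals)
    if eh is None or lad is None:
        synth_eh, synth_lad = synth_interval_table(bp_sizes, seed=seed)
        eh = eh if eh is not None else synth_eh
        lad = lad if lad is not None else synth_lad
    _check_class_conflicts(eh)

    names = list(bp_sizes)
    lengths = [int(round(bp_sizes[c] / bp_per_bead)) for c in names]
    bead_class = []
    lad_flag = []
    for chrom, n_beads in zip(names, lengths):
        cov = _per_bead_coverage(eh, chrom, n_beads, bp_per_bead,
                                 ["EU", "HET"])
        cls = np.where(cov["HET"] > bp_per_bead / 2.0, HET, EU).astype(np.int8)
        lcov = _per_bead_coverage(lad, chrom, n_beads, bp_per_bead, ["LAD"])
        lf = (lcov["LAD"] > bp_per_bead / 2.0) & (cls == EU)
        bead_class.append(cls)
        lad_flag.append(lf)
    return GenomeSpec(
        chain_names=names,
        chain_lengths=lengths,
        bead_class=np.concatenate(bead_class),
        lad_flag=np.concatenate(lad_flag),
        bp_per_bead=bp_per_bead,
    )


def _check_class_conflicts(eh: pd.DataFrame):
    """Error on overlapping intervals that assign contradictory classes."""
    offenders = []
    for chrom, sub in eh.groupby("chrom"):
        sub = sub.sort_values("start_bp").reset_index(drop=True)
        for k in range(len(sub) - 1):
            if (sub.loc[k + 1, "start_bp"] < sub.loc[k, "end_bp"]
                    and sub.loc[k + 1, "label"] != sub.loc[k, "label"]):
                offenders.append(
                    f"{chrom}:{sub.loc[k, 'start_bp']}-{sub.loc[k, 'end_bp']}"
                    f"({sub.loc[k, 'label']}) vs "
                    f"{sub.loc[k + 1, 'start_bp']}-{sub.loc[k + 1, 'end_bp']}"
                    f"({sub.loc[k + 1, 'label']})"
                )
    if offenders:
        raise ValueError(
            "contradictory overlapping class intervals: " + "; ".join(offenders)
        )


def build_lamina_shell(Rc, bead_spacing=1.5, thickness=1.0) -> np.ndarray:
    """Quasi-uniform immobile lamin bead layer lining the confinement.

    Points are laid out on Fibonacci-spiral sphere layers with radii in
    [Rc - thickness, Rc]; the per-layer count is chosen so nearest-neighbor
    spacing tracks ``bead_spacing``.
    """
    if Rc <= 2.0:
        raise ValueError("Rc must exceed 2 sigma")
    if bead_spacing < 1.0:
        raise ValueError("shell spacing below 1 sigma would overlap beads")
    n_layers = max(1, int(thickness // bead_spacing) + (1 if thickness % bead_spacing > 1e-9 and thickness >= bead_spacing else 0))
    if thickness < bead_spacing:
        radii = [Rc - thickness / 2.0]
    else:
        radii = list(np.linspace(Rc - thickness + bead_spacing / 2.0,
                                 Rc - bead_spacing / 2.0, n_layers))
    layers = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for r in radii:
        n = max(12, int(round(4.0 * math.pi * r * r / bead_spacing ** 2)))
        i = np.arange(n)
        z = 1.0 - 2.0 * (i + 0.5) / n
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        phi = golden * i
        layers.append(
            np.stack([r * rho * np.cos(phi), r * rho * np.sin(phi), r * z],
                     axis=1)
        )
    return np.vstack(layers)


def add_lamina_shell(system: PolymerSystem, bead_spacing=1.5, thickness=1.0
                     ) -> PolymerSystem:
    """Append an immobile lamin shell to a confined system.

    The shell beads get their own chain id after the chromatin chains and a
    LAMIN bead type; they are excluded from the mobile mask and from all
    chain-level analyses.
    """
    Rc = system.confinement_radius
    if not math.isfinite(Rc):
        raise ValueError("system must be confined to add a lamina shell")
    shell = build_lamina_shell(Rc + 0.5, bead_spacing=bead_spacing,
                               thickness=thickness)
    # shell sits just outside the chromatin wall edge (Rc - 0.5) so that
    # LJ contact with LAD beads is possible without crowding the interior
    n_shell = len(shell)
    shell_chain = np.full(n_shell, system.n_chains, np.int32)
    return PolymerSystem(
        positions=np.vstack([system.positions, shell]),
        chain_id=np.concatenate([system.chain_id, shell_chain]),
        bead_type=np.concatenate(
            [system.bead_type, np.full(n_shell, LAMIN, np.int8)]
        ),
        lad_flag=np.concatenate([system.lad_flag, np.zeros(n_shell, bool)]),
        velocities=np.vstack([system.velocities, np.zeros((n_shell, 3))]),
        bonds=system.bonds.copy(),
        angle_triples=system.angle_triples.copy(),
        confinement_radius=Rc,
    )
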