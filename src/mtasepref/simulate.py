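"""Synthetic substrate libraries, methylation kinetics and hairpin bisulfite reads.

The simulator is the ground-truth side of the analysis: substrate molecules
with randomized flanks are methylated under a known multiplicative rate model
and emitted as stem-loop-linked bisulfite reads, together with a manifest that
records every molecule's context, effective rate and methylation outcome.

Rate model
----------
Each molecule's target C is methylated as a first-order reaction with

    k_eff = k_base * motif_factor(variant) * prod_i f_i(N_i) * prod complex terms
    P(methylated at t) = 1 - exp(-k_eff * t)

where ``f_i(N)`` is the per-flank-position per-base rate multiplier, the motif
factor is 1 for the cognate motif (near-cognate factors are specified relative
to it, unlisted variants get 0) and optional non-multiplicative "complex"
terms couple pairs of flank positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ConfigurationError, SubstrateDesign
from .dna import BASE_INDEX, BASES, decode_matrix, encode_matrix, reverse_complement


@dataclass
class PreferenceModel:
    """Ground-truth (or fitted) multiplicative flanking/motif rate model.

    Parameters
    ----------
    motif
        Cognate recognition motif.
    target_index
        1-based position of the methylated C within the motif.
    flank_factors
        ``{position: {base: factor}}`` for flank positions -m..-1, +1..+m
        (no position 0).  Positions not listed act as factor 1.
    motif_factors
        Rate factor per motif variant relative to the cognate (which is 1 by
        convention and need not be listed).
    complex_terms
        Optional ``{((pos_i, pos_j), (base_i, base_j)): factor}``
        non-multiplicative interactions between flank positions.
    k_base
        Baseline first-order rate constant of the cognate motif in an
        all-factors-1 context (per unit time).
    """

    motif: str
    target_index: int = 1
    flank_factors: dict[int, dict[str, float]] = field(default_factory=dict)
    motif_factors: dict[str, float] = field(default_factory=dict)
    complex_terms: dict[tuple[tuple[int, int], tuple[str, str]], float] = field(
        default_factory=dict
    )
    k_base: float = 1.0

    def __post_init__(self) -> None:
        if self.motif[self.target_index - 1] != "C":
            raise ConfigurationError("target_index must point at a C in the motif")
        if self.k_base < 0:
            raise ConfigurationError("k_base must be nonnegative")
        for pos, by_base in self.flank_factors.items():
            if pos == 0:
                raise ConfigurationError("flank positions exclude 0")
            if set(by_base) != set(BASES):
                raise ConfigurationError(
                    f"flank_factors[{pos}] must define all four bases"
                )
            if any(v < 0 for v in by_base.values()):
                raise ConfigurationError("rate factors must be nonnegative")
        if any(v < 0 for v in self.motif_factors.values()):
            raise ConfigurationError("motif factors must be nonnegative")
        self.motif_factors.setdefault(self.motif, 1.0)

    def motif_factor(self, variant: str) -> float:
        return self.motif_factors.get(variant, 0.0)

    def k_eff(self, window: str, design: SubstrateDesign) -> float:
        """Effective first-order rate for one molecule's variable window."""
        frame = design.frame_offsets(self.motif, self.target_index)
        variant = "".join(window[i] for i in frame)
        k = self.k_base * self.motif_factor(variant)
        for pos, by_base in self.flank_factors.items():
            off = design.flank_offset(pos, self.motif, self.target_index)
            k *= by_base[window[off]]
        for ((pi, pj), (bi, bj)), factor in self.complex_terms.items():
            oi = design.flank_offset(pi, self.motif, self.target_index)
            oj = design.flank_offset(pj, self.motif, self.target_index)
            if window[oi] == bi and window[oj] == bj:
                k *= factor
        return k

    def k_eff_batch(self, windows: np.ndarray, design: SubstrateDesign) -> np.ndarray:
        """Vectorised ``k_eff`` over an (n, window_len) base-index matrix."""
        n = windows.shape[0]
        frame = design.frame_offsets(self.motif, self.target_index)
        # motif factor per molecule
        k = np.zeros(n)
        cols = windows[:, list(frame)]
        for variant, factor in self.motif_factors.items():
            codes = np.array([BASE_INDEX[b] for b in variant], dtype=np.uint8)
            k[(cols == codes).all(axis=1)] = factor
        k *= self.k_base
        for pos, by_base in self.flank_factors.items():
            off = design.flank_offset(pos, self.motif, self.target_index)
            lut = np.array([by_base[b] for b in BASES])
            k *= lut[windows[:, off]]
        for ((pi, pj), (bi, bj)), factor in self.complex_terms.items():
            oi = design.flank_offset(pi, self.motif, self.target_index)
            oj = design.flank_offset(pj, self.motif, self.target_index)
            hit = (windows[:, oi] == BASE_INDEX[bi]) & (
                windows[:, oj] == BASE_INDEX[bj]
            )
            k[hit] *= factor
        return k

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "target_index": self.target_index,
            "k_base": self.k_base,
            "flank_factors": {int(p): dict(b) for p, b in self.flank_factors.items()},
            "motif_factors": dict(self.motif_factors),
            "complex_terms": [
                {"positions": list(pp), "bases": list(bb), "factor": f}
                for (pp, bb), f in self.complex_terms.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreferenceModel":
        complex_terms = {
            (tuple(t["positions"]), tuple(t["bases"])): t["factor"]
            for t in d.get("complex_terms", [])
        }
        return cls(
            motif=d["motif"],
            target_index=d.get("target_index", 1),
            flank_factors={
                int(p): dict(b) for p, b in d.get("flank_factors", {}).items()
            },
            motif_factors=dict(d.get("motif_factors", {})),
            complex_terms=complex_terms,
            k_base=d.get("k_base", 1.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PreferenceModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def random_preference_model(
    motif: str,
    target_index: int,
    positions,
    seed: int,
    low: float = 0.5,
    high: float = 2.0,
    k_base: float = 1.0,
) -> PreferenceModel:
    """Draw flank factors log-uniformly in [low, high] for the given positions."""
    rng = np.random.default_rng(seed)
    flank = {
        int(p): {
            b: float(np.exp(rng.uniform(np.log(low), np.log(high)))) for b in BASES
        }
        for p in positions
    }
    return PreferenceModel(
        motif=motif, target_index=target_index, flank_factors=flank, k_base=k_base
    )


@dataclass
class MoleculeRecord:
    """One double-stranded substrate molecule."""

    molecule_id: str
    top_strand: str
    methylated: bool = False
    hemimethylated_start: bool = False

    @property
    def bottom_strand(self) -> str:
        return reverse_complement(self.top_strand)


@dataclass
class GroundTruthManifest:
    """Per-molecule ground truth plus the generating model and conditions.

    ``table`` columns: molecule_id, window, variant, k_eff, p_meth, methylated.
    """

    table: pd.DataFrame
    model: PreferenceModel
    design: SubstrateDesign
    t: float
    seed: int

    @property
    def n_methylated(self) -> int:
        return int(self.table["methylated"].sum())

    def expected_k(self, window: str) -> float:
        """Recompute k_eff from the stored model (manifest invariant)."""
        return self.model.k_eff(window, self.design)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model_motif={self.model.motif} t={self.t} seed={self.seed}\n")
            self.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def _random_windows(
    design: SubstrateDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, window_len) base-index matrix of variable windows."""
    win = rng.integers(0, 4, size=(n, design.window_len), dtype=np.uint8)
    for off, base in design.fixed.items():
        win[:, off] = BASE_INDEX[base]
    if design.cn_mix_ratio is not None:
        off = design.target_offset + 1
        if off < design.window_len and off not in design.fixed:
            is_h = rng.random(n) < design.cn_mix_ratio
            h = np.array([BASE_INDEX[b] for b in "ACT"], dtype=np.uint8)[
                rng.integers(0, 3, size=n)
            ]
            win[:, off] = np.where(is_h, h, BASE_INDEX["G"])
    return win


def generate_library(
    design: SubstrateDesign, n_molecules: int, seed: int
) -> list[MoleculeRecord]:
    """Draw ``n_molecules`` substrate molecules from the design.

    Randomized positions are i.i.d. uniform over {A,C,G,T}; for CN libraries
    the base after the target C follows the CpH:CpG mix.  Deterministic for a
    given seed.
    """
    if n_molecules < 1:
        raise ConfigurationError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    windows = decode_matrix(_random_windows(design, n_molecules, rng))
    stub = design.right_arm[: design.right_keep]
    return [
        MoleculeRecord(
            molecule_id=f"mol{i}",
            top_strand=design.left_arm + w + stub,
            hemimethylated_start=design.hemimethylated_start,
        )
        for i, w in enumerate(windows)
    ]


# ---------------------------------------------------------------------------
# methylation kinetics
# ---------------------------------------------------------------------------

def simulate_methylation(
    molecules: list[MoleculeRecord],
    model: PreferenceModel,
    design: SubstrateDesign,
    t: float,
    seed: int,
) -> tuple[list[MoleculeRecord], GroundTruthManifest]:
    """Methylate target Cs with P = 1 - exp(-k_eff * t).

    Returns new molecule records plus the ground-truth manifest.  Non-target
    cytosines are never touched; deterministic for a given seed.
    """
    if t < 0:
        raise ValueError("reaction time t must be nonnegative")
    rng = np.random.default_rng(seed)
    ws, wl = design.window_start, design.window_len
    windows = [m.top_strand[ws : ws + wl] for m in molecules]
    mat = encode_matrix(windows)
    k = model.k_eff_batch(mat, design) if molecules else np.empty(0)
    p = -np.expm1(-k * t)
    meth = rng.random(len(molecules)) < p
    frame = design.frame_offsets(model.motif, model.target_index)
    variants = ["".join(w[i] for i in frame) for w in windows]
    out = [
        MoleculeRecord(
            molecule_id=m.molecule_id,
            top_strand=m.top_strand,
            methylated=bool(b),
            hemimethylated_start=m.hemimethylated_start,
        )
        for m, b in zip(molecules, meth)
    ]
    table = pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "window": windows,
            "variant": variants,
            "k_eff": k,
            "p_meth": p,
            "methylated": meth,
        }
    )
    return out, GroundTruthManifest(
        table=table, model=model, design=design, t=t, seed=seed
    )


def time_for_target_methylation(
    model: PreferenceModel,
    design: SubstrateDesign,
    target_fraction: float,
    n_sample: int = 2000,
    seed: int = 0,
) -> float:
    """Reaction time at which the library-average methylation is approximately
    ``target_fraction`` (root-finding on a sampled set of contexts)."""
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    mat = _random_windows(design, n_sample, rng)
    ks = model.k_eff_batch(mat, design)

    def excess(t: float) -> float:
        return float(np.mean(-np.expm1(-ks * t))) - target_fraction

    hi = 1.0
    while excess(hi) < 0 and hi < 1e9:
        hi *= 10
    return float(brentq(excess, 0.0, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# bisulfite conversion and hairpin reads
# ---------------------------------------------------------------------------

def bisulfite_and_read(
    molecules: list[MoleculeRecord],
    design: SubstrateDesign,
    conv_rate: float = 0.995,
    inappropriate_conv_rate: float = 0.0,
    error_rate: float = 0.0,
    read_len: int | None = None,
    seed: int = 0,
    duplicate_fraction: float = 0.0,
    duplicate_copies: int = 2,
    quality_model: str = "constant",
    q_good: int = 37,
    q_bad: int = 11,
    bad_base_fraction: float = 0.05,
) -> list[SeqRecord]:
    """Emit one hairpin bisulfite read per molecule (plus optional duplicates).

    The read is top strand + stem-loop + bottom strand, read 5'->3' through
    the hairpin and truncated to ``read_len`` (default: the full hairpin
    span).  Every unmethylated C on the continuous strand converts to T with
    probability ``conv_rate``; methylated Cs convert with
    ``inappropriate_conv_rate``.  Substitution sequencing errors are applied
    at ``error_rate``.  Qualities are constant Q``q_good`` or drawn from a
    two-state good/bad per-base model.
    """
    for name, r in (
        ("conv_rate", conv_rate),
        ("inappropriate_conv_rate", inappropriate_conv_rate),
        ("error_rate", error_rate),
        ("duplicate_fraction", duplicate_fraction),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if quality_model not in ("constant", "two_state"):
        raise ConfigurationError(f"unknown quality model {quality_model!r}")
    if read_len is None:
        read_len = design.read_span
    if read_len < design.top_span:
        raise ConfigurationError("read_len shorter than the top-strand span")
    if not molecules:
        return []
    rng = np.random.default_rng(seed)
    loop = design.stem_loop
    top_span, loop_len = design.top_span, len(loop)
    full = [
        m.top_strand + loop + reverse_complement(m.top_strand) for m in molecules
    ]
    mat = encode_matrix(full)
    n, span = mat.shape
    c_idx, t_idx = BASE_INDEX["C"], BASE_INDEX["T"]

    # conversion probability per position: conv_rate for unmethylated Cs,
    # inappropriate_conv_rate at methylated positions
    rate = np.where(mat == c_idx, conv_rate, 0.0)
    target_col = design.window_start + design.target_offset
    meth_rows = np.array([m.methylated for m in molecules])
    rate[meth_rows, target_col] = np.where(
        mat[meth_rows, target_col] == c_idx, inappropriate_conv_rate, 0.0
    )
    if design.bottom_methyl_offset is not None:
        hemi_rows = np.array([m.hemimethylated_start for m in molecules])
        top_off = design.window_start + design.bottom_methyl_offset
        bcol = top_span + loop_len + (top_span - 1 - top_off)
        rate[hemi_rows, bcol] = np.where(
            mat[hemi_rows, bcol] == c_idx, inappropriate_conv_rate, 0.0
        )
    convert = rng.random((n, span)) < rate
    mat = np.where(convert, t_idx, mat).astype(np.uint8)

    if error_rate > 0:
        err = rng.random((n, span)) < error_rate
        shift = rng.integers(1, 4, size=(n, span)).astype(np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat).astype(np.uint8)

    seqs = decode_matrix(mat[:, :read_len])
    eff_len = min(read_len, span)
    if quality_model == "two_state":
        bad = rng.random((n, eff_len)) < bad_base_fraction
        quals = np.where(bad, q_bad, q_good)
    else:
        quals = np.full((n, eff_len), q_good)
    dup = (
        rng.random(n) < duplicate_fraction
        if duplicate_fraction > 0
        else np.zeros(n, dtype=bool)
    )

    records: list[SeqRecord] = []
    for i, mol in enumerate(molecules):
        q = [int(v) for v in quals[i]]
        n_copies = duplicate_copies if dup[i] else 1
        for c in range(n_copies):
            rid = mol.molecule_id if c == 0 else f"{mol.molecule_id}.dup{c}"
            rec = SeqRecord(Seq(seqs[i]), id=rid, description="")
            rec.letter_annotations["phred_quality"] = q
            records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path) -> int:
    return SeqIO.write(records, str(path), "fastq")


def simulate_experiment(
    design: SubstrateDesign,
    model: PreferenceModel,
    n_molecules: int,
    t: float,
    seed: int,
    **read_kwargs,
) -> tuple[list[SeqRecord], GroundTruthManifest]:
    """Library generation + methylation + read emission from one seed.

    Sub-seeds for the three stochastic stages are derived from ``seed`` so the
    whole experiment is reproducible from a single integer.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    mols = generate_library(design, n_molecules, seeds[0])
    mols, manifest = simulate_methylation(mols, design=design, model=model, t=t, seed=seeds[1])
    reads = bisulfite_and_read(mols, design, seed=seeds[2], **read_kwargs)
    return reads, manifest
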