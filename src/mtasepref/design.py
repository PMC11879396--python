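"""Substrate library designs for deep-enzymology methylation experiments.

A substrate molecule is a double-stranded oligo with constant scaffold arms
around a variable window that carries the methylation target.  Two designs are
used in practice:

* ``cn_design`` — the specificity library: the target C sits in a CN
  dinucleotide inside a fully randomized window (10 N upstream, 10 N
  downstream).  The base after the target C is a mix of CpH and CpG molecules
  (default 3:1, H drawn uniformly from {A,C,T}), so near-cognate motifs of any
  enzyme occur at usable frequency.
* ``motif_design`` — the flanking-preference library: the enzyme's full
  recognition motif is fixed in the centre with 9 randomized bases on each
  side.

After methylation the molecule is restriction-digested and a stem-loop oligo
is ligated to the cut end, so a single sequencing read traverses top strand,
loop and bottom strand.  The digestion itself is abstracted: the design keeps
a 3' arm stub sized so that the complete hairpin spans ``hairpin_length``
nucleotides (default 128), which is the span a trimmed read covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .dna import is_dna

# constant scaffold sequences of the oligo substrates
LEFT_ARM = "GAGTGTGACTAGGCTCTCACTGCC"
RIGHT_ARM = "GAGAGGAGACCTAGTGAGAAG"
STEM_LOOP = "GAGAAGGGATGTGGATACACATCCCT"

#: enzyme -> (recognition motif, 1-based index of the methylated C, CN-library
#: analysis frame as offsets of the frame start relative to the target C)
ENZYMES: dict[str, tuple[str, int]] = {
    "M.SssI": ("CG", 1),
    "M.HhaI": ("GCGC", 2),
    "M.HaeIII": ("GGCC", 3),
    "M.HpaII": ("CCGG", 2),
    "M.MspI": ("CCGG", 1),
    "M.AluI": ("AGCT", 3),
}


class ConfigurationError(ValueError):
    """Invalid substrate design or run configuration."""


@dataclass(frozen=True)
class SubstrateDesign:
    """Layout of one substrate library.

    Parameters
    ----------
    name
        Free-form label (e.g. ``"CNrand"`` or ``"GCGCrand"``).
    window_len
        Length of the variable window between the arms.
    target_offset
        0-based offset of the fixed target C within the window.
    fixed
        Constant bases inside the window (window offset -> base), e.g. the
        recognition motif of a preference library.  Must include the target C.
    cn_mix_ratio
        For CN libraries: fraction of CpH molecules at the position after the
        target C (remainder CpG); ``None`` means that position is a plain N
        (or fixed).  H is drawn uniformly from {A,C,T}.
    hemimethylated_start
        If True, the bottom-strand C pairing with the top base at
        ``bottom_methyl_offset`` is pre-methylated (hemimethylated substrate,
        used to focus activity on the top strand of palindromic motifs).
    hairpin_length
        Total span of top strand + stem-loop + bottom strand after digestion
        and loop ligation; determines how much of the 3' arm is retained.
    """

    name: str
    window_len: int
    target_offset: int
    fixed: dict[int, str] = field(default_factory=dict)
    cn_mix_ratio: float | None = None
    hemimethylated_start: bool = False
    bottom_methyl_offset: int | None = None
    left_arm: str = LEFT_ARM
    right_arm: str = RIGHT_ARM
    stem_loop: str = STEM_LOOP
    hairpin_length: int = 128

    def __post_init__(self) -> None:
        for arm in (self.left_arm, self.right_arm, self.stem_loop):
            if not is_dna(arm):
                raise ConfigurationError(f"scaffold sequence {arm!r} is not DNA")
        if not 0 <= self.target_offset < self.window_len:
            raise ConfigurationError("target_offset outside the variable window")
        if self.fixed.get(self.target_offset) != "C":
            raise ConfigurationError("design must fix a target C inside the window")
        for off, base in self.fixed.items():
            if not 0 <= off < self.window_len:
                raise ConfigurationError(f"fixed base offset {off} outside window")
            if base not in "ACGT":
                raise ConfigurationError(f"fixed base {base!r} is not a DNA base")
        if self.cn_mix_ratio is not None and not 0.0 <= self.cn_mix_ratio <= 1.0:
            raise ConfigurationError("cn_mix_ratio must be in [0, 1]")
        if self.hemimethylated_start and self.bottom_methyl_offset is None:
            raise ConfigurationError(
                "hemimethylated_start requires bottom_methyl_offset"
            )
        if self.right_keep < 3:
            raise ConfigurationError(
                "hairpin_length too short for this window and left arm"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def window_start(self) -> int:
        return len(self.left_arm)

    @property
    def right_keep(self) -> int:
        """Retained 3' arm stub length after the abstracted digestion."""
        top_span = (self.hairpin_length - len(self.stem_loop)) // 2
        return min(len(self.right_arm), top_span - len(self.left_arm) - self.window_len)

    @property
    def top_span(self) -> int:
        """Length of the top strand of the digested molecule."""
        return len(self.left_arm) + self.window_len + self.right_keep

    @property
    def read_span(self) -> int:
        """Full hairpin span: top strand + loop + bottom strand."""
        return 2 * self.top_span + len(self.stem_loop)

    @property
    def layout(self) -> list[str]:
        """Per-position tags over the top strand: constant | randomized | target-motif."""
        tags = ["constant"] * len(self.left_arm)
        for i in range(self.window_len):
            tags.append("target-motif" if i in self.fixed else "randomized")
        tags += ["constant"] * self.right_keep
        return tags

    @property
    def target_motif(self) -> str:
        """Fixed bases of the window in order (the embedded motif, if any)."""
        return "".join(self.fixed[i] for i in sorted(self.fixed))

    def flank_offset(self, position: int, motif: str, target_index: int) -> int:
        """Window offset of flank ``position`` (-m..-1, +1..+m; no 0) relative
        to the frame of ``motif`` whose ``target_index``-th base (1-based) is
        the fixed target C."""
        if position == 0:
            raise ValueError("flank positions are numbered -m..-1, +1..+m; no 0")
        frame_start = self.target_offset - (target_index - 1)
        if position < 0:
            off = frame_start + position
        else:
            off = frame_start + len(motif) + position - 1
        if not 0 <= off < self.window_len:
            raise ValueError(f"flank position {position} outside the window")
        return off

    def frame_offsets(self, motif: str, target_index: int) -> range:
        """Window offsets occupied by the motif frame around the target C."""
        start = self.target_offset - (target_index - 1)
        if start < 0 or start + len(motif) > self.window_len:
            raise ValueError("motif frame does not fit in the window")
        return range(start, start + len(motif))

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "window_len": self.window_len,
            "target_offset": self.target_offset,
            "fixed": dict(self.fixed),
            "cn_mix_ratio": self.cn_mix_ratio,
            "hemimethylated_start": self.hemimethylated_start,
            "bottom_methyl_offset": self.bottom_methyl_offset,
            "left_arm": self.left_arm,
            "right_arm": self.right_arm,
            "stem_loop": self.stem_loop,
            "hairpin_length": self.hairpin_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstrateDesign":
        d = dict(d)
        d["fixed"] = {int(k): v for k, v in d.get("fixed", {}).items()}
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SubstrateDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def cn_design(
    cn_mix_ratio: float = 0.75,
    n_upstream: int = 10,
    n_downstream: int = 10,
    **kwargs,
) -> SubstrateDesign:
    """Specificity library: N10-C[N]-N10 with a CpH:CpG mix after the target C.

    ``cn_mix_ratio`` is the CpH fraction; the default 0.75 is the 3:1 CpH:CpG
    mixing of the two synthesised oligo pools.
    """
    window_len = n_upstream + 2 + n_downstream
    return SubstrateDesign(
        name="CNrand",
        window_len=window_len,
        target_offset=n_upstream,
        fixed={n_upstream: "C"},
        cn_mix_ratio=cn_mix_ratio,
        **kwargs,
    )


def motif_design(
    motif: str,
    target_index: int,
    n_flank: int = 9,
    hemimethylated: bool = False,
    **kwargs,
) -> SubstrateDesign:
    """Flanking-preference library: N9-motif-N9 with the full motif fixed.

    ``target_index`` is the 1-based position of the methylated C within the
    motif.  With ``hemimethylated=True`` (CG-type substrates) the bottom-strand
    C of the palindromic core is pre-methylated.
    """
    if not is_dna(motif):
        raise ConfigurationError(f"motif {motif!r} is not DNA")
    if "C" not in motif:
        raise ConfigurationError("target motif must contain at least one C")
    if not 1 <= target_index <= len(motif) or motif[target_index - 1] != "C":
        raise ConfigurationError("target_index must point at a C in the motif")
    fixed = {n_flank + i: b for i, b in enumerate(motif)}
    bottom_off = None
    if hemimethylated:
        # bottom-strand methylated C pairs with a top-strand G in the motif;
        # for palindromic motifs this is the base complementary to the target C
        gpos = [i for i, b in enumerate(motif) if b == "G"]
        if not gpos:
            raise ConfigurationError("hemimethylated design needs a G in the motif")
        sym = len(motif) - target_index  # palindromic partner, 0-based
        bottom_off = n_flank + (sym if motif[sym] == "G" else gpos[0])
    return SubstrateDesign(
        name=f"{motif}rand",
        window_len=2 * n_flank + len(motif),
        target_offset=n_flank + target_index - 1,
        fixed=fixed,
        hemimethylated_start=hemimethylated,
        bottom_methyl_offset=bottom_off,
        **kwargs,
    )


def enzyme_design(enzyme: str, library: str = "motif", **kwargs) -> SubstrateDesign:
    """Design for a registered enzyme: ``library`` is 'motif' or 'cn'."""
    if enzyme not in ENZYMES:
        raise ConfigurationError(
            f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}"
        )
    motif, tsp = ENZYMES[enzyme]
    if library == "cn":
        return cn_design(**kwargs)
    if library == "motif":
        return motif_design(motif, tsp, **kwargs)
    raise ConfigurationError("library must be 'motif' or 'cn'")
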