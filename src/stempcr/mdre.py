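"""Methylation-dependent restriction digestion in silico.

Methylation-dependent restriction endonucleases (MDREs) such as GlaI,
MspJI and FspEI cleave DNA only when their recognition context carries a
5-methylcytosine.  GlaI recognizes the palindromic duplex
5'-R(5mC)GY-3' / 3'-YG(5mC)R-5' and cuts the phosphodiester bond between
the methylated C and the G on both strands, leaving blunt ends.  The
downstream fragment therefore starts with a defined 5' terminus whose
identity encodes the methylation event; that terminus is the template
(P1) on which a terminal-mediated PCR assay is built.

This module simulates all-or-none digestion of symmetrically methylated
sequences, decides whether a given CpG can support an assay (is the site
cleavable, and is the template immediately 3' of the cut free of further
cleavable sites?), applies the nearby-site substitution rule, and
computes the fraction of methylated CpG dyads an enzyme can reach under
a base-composition model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "MethylSequence",
    "MDRESpec",
    "Fragment",
    "AssayabilityReport",
    "SiteCandidate",
    "load_enzyme",
    "enzyme_registry",
    "find_mdre_sites",
    "digest",
    "is_site_assayable",
    "substitute_adjacent",
    "coverage_estimate",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MethylSequence:
    """Uppercase DNA with symmetric CpG methylation marks.

    ``methylated_cpgs`` holds 1-based plus-strand positions of the C of
    each methylated CpG dyad; marks are symmetric (both strands
    methylated) by construction.
    """

    name: str
    sequence: str
    methylated_cpgs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "methylated_cpgs", frozenset(int(p) for p in self.methylated_cpgs))
        bad = set(seq) - set(_BASES)
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        for p in self.methylated_cpgs:
            if not 1 <= p < len(seq):
                raise ValueError(f"methylated position {p} outside [1, {len(seq) - 1}]")
            if seq[p - 1 : p + 1] != "CG":
                raise ValueError(f"position {p} does not start a CG dinucleotide")

    def __len__(self) -> int:
        return len(self.sequence)

    def unmethylated(self) -> "MethylSequence":
        """Copy with every methylation mark stripped."""
        return MethylSequence(self.name, self.sequence, frozenset())

    def reverse_complement(self) -> "MethylSequence":
        """Mirror-image sequence with marks remapped to the other strand.

        A symmetric mCpG at plus position p maps to position L - p on the
        reverse complement (the C of the same dyad read from the other
        strand).
        """
        L = len(self.sequence)
        marks = frozenset(L - p for p in self.methylated_cpgs)
        return MethylSequence(self.name + "_rc", reverse_complement(self.sequence), marks)


@dataclass(frozen=True)
class MDRESpec:
    """Recognition and cut rule of a methylation-dependent enzyme.

    ``motif`` is an IUPAC string read 5'->3' on the strand carrying the
    methylcytosine, with ``mc_index`` the 0-based offset of that mC
    within the motif.  ``strand_mode`` is "both" when the duplex motif
    must be satisfied on both strands (GlaI's palindrome) or "either"
    when recognition on one strand suffices (MspJI, FspEI).
    ``cut_offset`` places the cleaved phosphodiester bond immediately 3'
    of plus-strand position (mC + cut_offset); ``None`` means the cut
    placement is not modeled (recognition-only enzymes).
    """

    name: str
    motif: str
    mc_index: int
    strand_mode: str = "either"
    cut_offset: int | None = None
    end_chemistry: str = "blunt"

    def __post_init__(self):
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if not 0 <= self.mc_index < len(motif):
            raise ValueError("mc_index outside motif")
        for ch in motif:
            if ch not in ambiguous_dna_values:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif")
        if "C" not in ambiguous_dna_values[motif[self.mc_index]]:
            raise ValueError("motif position mc_index cannot be a cytosine")
        if self.strand_mode not in ("both", "either"):
            raise ValueError("strand_mode must be 'both' or 'either'")


@dataclass(frozen=True)
class Fragment:
    """Digestion product; 1-based inclusive coordinates on the parent."""

    sequence: str
    start: int
    end: int
    five_prime_is_cut: bool = False


@dataclass(frozen=True)
class AssayabilityReport:
    site: int
    assayable: bool
    reason: str  # ok | not_recognized | template_interrupted | template_too_short
    p1_template: str = ""
    substitute: str | None = None


@dataclass(frozen=True)
class SiteCandidate:
    """A CpG site with genomic coordinate and assayability verdict."""

    site_id: str
    pos: int
    assayable: bool


def _registry_raw() -> dict:
    with resources.files("stempcr.data").joinpath("enzymes.json").open() as fh:
        return json.load(fh)


def enzyme_registry() -> dict[str, MDRESpec]:
    """All enzymes shipped in the JSON registry, keyed by name."""
    return {name: MDRESpec(name=name, **entry) for name, entry in _registry_raw().items()}


def load_enzyme(name: str) -> MDRESpec:
    reg = _registry_raw()
    try:
        entry = reg[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; registry has {sorted(reg)}") from None
    return MDRESpec(name=name, **entry)


def _matches_iupac(window: str, motif: str) -> bool:
    return len(window) == len(motif) and all(
        b in ambiguous_dna_values[m] for b, m in zip(window, motif)
    )


def _plus_match(seq: str, c_pos: int, enzyme: MDRESpec) -> bool:
    # c_pos: 1-based position of the mC on this strand
    start = c_pos - 1 - enzyme.mc_index
    end = start + len(enzyme.motif)
    if start < 0 or end > len(seq):
        return False
    return _matches_iupac(seq[start:end], enzyme.motif)


def _site_cleavable(seq: MethylSequence, p: int, enzyme: MDRESpec) -> bool:
    s = seq.sequence
    L = len(s)
    plus = _plus_match(s, p, enzyme)
    # the minus-strand mC of a symmetric dyad sits opposite the G at p+1,
    # i.e. at position L - p of the reverse complement (1-based)
    minus = _plus_match(reverse_complement(s), L - p, enzyme)
    if enzyme.strand_mode == "both":
        return plus and minus
    return plus or minus


def find_mdre_sites(seq: MethylSequence, enzyme: MDRESpec) -> list[int]:
    """Plus-strand C positions of methylated CpGs the enzyme can cleave.

    Unmethylated CG contexts never match: recognition is methylation
    dependent.
    """
    return [p for p in sorted(seq.methylated_cpgs) if _site_cleavable(seq, p, enzyme)]


def cut_positions(seq: MethylSequence, enzyme: MDRESpec) -> list[int]:
    """Plus-strand coordinates q such that the cut falls between q and q+1."""
    if enzyme.cut_offset is None:
        raise ValueError(f"enzyme {enzyme.name} has no cut rule defined")
    L = len(seq)
    cuts = sorted({p + enzyme.cut_offset for p in find_mdre_sites(seq, enzyme)})
    return [q for q in cuts if 1 <= q < L]


def digest(seq: MethylSequence, enzyme: MDRESpec) -> list[Fragment]:
    """Cut at every cleavable site; fragments tile the parent exactly.

    GlaI cuts between the methylated C and the G (blunt), so the
    downstream fragment starts with the G of the dyad and carries the
    assay-defining 5' terminus (flagged ``five_prime_is_cut``).
    """
    s = seq.sequence
    bounds = [0] + cut_positions(seq, enzyme) + [len(s)]
    frags = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        frags.append(Fragment(s[a:b], a + 1, b, five_prime_is_cut=i > 0))
    return frags


def is_site_assayable(
    seq: MethylSequence,
    site: int,
    enzyme: MDRESpec,
    min_template: int = 40,
) -> AssayabilityReport:
    """Decide whether a methylated CpG can seed a terminal-mediated assay.

    The site must itself be cleavable, and the P1 template - the
    ``min_template`` bases immediately 3' of the cut on the cleaved
    strand - must contain no further cleavable position, otherwise the
    template is fragmented before a primer can capture it.
    """
    if site not in seq.methylated_cpgs:
        raise ValueError(f"position {site} is not a methylated CpG of {seq.name}")
    if enzyme.cut_offset is None:
        raise ValueError(f"enzyme {enzyme.name} has no cut rule defined")
    if not _site_cleavable(seq, site, enzyme):
        return AssayabilityReport(site, False, "not_recognized")
    cut = site + enzyme.cut_offset  # cut between cut and cut+1
    if cut + min_template > len(seq):
        return AssayabilityReport(site, False, "template_too_short")
    template = seq.sequence[cut : cut + min_template]
    interrupting = [
        q
        for q in find_mdre_sites(seq, enzyme)
        if q != site and cut + 1 <= q + enzyme.cut_offset <= cut + min_template - 1
    ]
    if interrupting:
        return AssayabilityReport(site, False, "template_interrupted", template)
    return AssayabilityReport(site, True, "ok", template)


def substitute_adjacent(
    target: SiteCandidate | tuple,
    candidates: Iterable[SiteCandidate | tuple],
    max_dist: int = 100,
) -> SiteCandidate | None:
    """Nearest assayable neighbor within ``max_dist`` bp (inclusive).

    Mirrors the replacement of non-designable CpGs by co-methylated
    neighbors; distance ties break toward the lower coordinate.
    Returns ``None`` when no candidate qualifies.
    """
    if not isinstance(target, SiteCandidate):
        target = SiteCandidate(*target)
    best: SiteCandidate | None = None
    for cand in candidates:
        if not isinstance(cand, SiteCandidate):
            cand = SiteCandidate(*cand)
        if not cand.assayable or cand.pos == target.pos:
            continue
        d = abs(cand.pos - target.pos)
        if d > max_dist:
            continue
        if (
            best is None
            or d < abs(best.pos - target.pos)
            or (d == abs(best.pos - target.pos) and cand.pos < best.pos)
        ):
            best = cand
    return best


def _dyad_context(up: str, down: str) -> MethylSequence:
    seq = up + "CG" + down
    return MethylSequence("dyad", seq, frozenset({len(up) + 1}))


def coverage_estimate(
    enzyme: MDRESpec,
    model: Mapping[str, float] | Sequence | None = None,
    *,
    method: str = "analytic",
    n_dyads: int = 100_000,
    seed: int = 0,
) -> float:
    """Fraction of symmetrically methylated CpG dyads the enzyme cleaves.

    ``model`` is either a base-frequency mapping for iid flanks (default
    uniform) or an explicit list of dyad contexts, each a
    ``MethylSequence`` or ``(sequence, c_position)`` pair.  The analytic
    mode enumerates every flank combination exactly (the motif reach is
    at most a few bases, so the enumeration is small); ``method="mc"``
    draws ``n_dyads`` seeded random contexts as an independent check.
    """
    if model is None:
        model = {b: 0.25 for b in _BASES}
    if isinstance(model, Mapping):
        freqs = {b: float(model.get(b, 0.0)) for b in _BASES}
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base frequencies sum to {total}, not 1")
        reach = len(enzyme.motif)
        if method == "analytic":
            covered = 0.0
            for up in itertools.product(_BASES, repeat=reach):
                p_up = np.prod([freqs[b] for b in up])
                if p_up == 0.0:
                    continue
                for down in itertools.product(_BASES, repeat=reach):
                    p = p_up * np.prod([freqs[b] for b in down])
                    if p == 0.0:
                        continue
                    dyad = _dyad_context("".join(up), "".join(down))
                    if _site_cleavable(dyad, reach + 1, enzyme):
                        covered += p
            return float(covered)
        if method == "mc":
            rng = np.random.default_rng(seed)
            probs = [freqs[b] for b in _BASES]
            hits = 0
            flanks = rng.choice(list(_BASES), size=(n_dyads, 2 * reach), p=probs)
            for row in flanks:
                dyad = _dyad_context("".join(row[:reach]), "".join(row[reach:]))
                if _site_cleavable(dyad, reach + 1, enzyme):
                    hits += 1
            return hits / n_dyads
        raise ValueError(f"unknown method {method!r}")
    # explicit list of contexts
    contexts = list(model)
    if not contexts:
        raise ValueError("empty context list")
    hits = 0
    for ctx in contexts:
        if isinstance(ctx, MethylSequence):
            dyad, pos = ctx, min(ctx.methylated_cpgs)
        else:
            seq, pos = ctx
            dyad = MethylSequence("ctx", seq, frozenset({int(pos)}))
        if _site_cleavable(dyad, pos, enzyme):
            hits += 1
    return hits / len(contexts)
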