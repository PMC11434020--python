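"""Terminal-mediated PCR primer design and hairpin thermodynamics.

A digestion-derived template (P1) with a defined 5' terminus is assayed
with a tailor-designed foldable primer (TFP) built from three regions:

* AP  - an artificial, target-independent primer sequence;
* FR  - a folding region that will later form the hairpin stem;
* CRc - a capture region, the reverse complement of the first bases of
  P1, so the TFP anneals flush to the cut terminus.

Across the linear PCR phase the TFP-primed strand accumulates, at its
3' end, the reverse complement of its own folding region (FRc); this
net product (P2) is modeled directly here.  P2 self-folds into P3 by
pairing FR with FRc, and self-primes into P4, a complete hairpin with
no 3' overhang, which seeds exponential amplification between AP and a
target-specific primer (TSP).

A design is accepted when the FR:FRc stem is stable at the PCR
annealing temperature: stem melting temperature strictly above the
threshold (66 C by default) and folding free energy below zero.  Stem
thermodynamics use the unified SantaLucia nearest-neighbor DNA
parameters (via Biopython's tables) with a monovalent-salt entropy
correction and a hairpin-loop penalty; the hairpin is unimolecular, so
Tm = dH / dS without a concentration term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Seq import reverse_complement
from Bio.SeqUtils import MeltingTemp as mt

__all__ = [
    "TfpDesign",
    "HairpinReport",
    "AmpliconDesign",
    "build_tfp",
    "fold_report",
    "amplicon_predict",
    "stem_thermo",
]

_COMP = str.maketrans("ACGT", "TGCA")

#: hairpin loop dG37 penalties (kcal/mol) by loop length, standard DNA
#: loop-length table; intermediate sizes are interpolated, larger loops
#: extrapolated logarithmically.
_LOOP_DG37: Mapping[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.1, 9: 4.2, 10: 4.3,
    12: 4.5, 14: 4.6, 16: 4.7, 18: 4.8, 20: 4.9, 25: 5.2, 30: 5.4,
}
_R = 1.987e-3  # kcal / (mol K)
_T37 = 310.15


def _loop_dg37(n: int) -> float:
    if n < 3:
        raise ValueError("hairpin loop needs at least 3 unpaired bases")
    sizes = sorted(_LOOP_DG37)
    if n in _LOOP_DG37:
        return _LOOP_DG37[n]
    if n > sizes[-1]:
        return _LOOP_DG37[sizes[-1]] + 1.75 * _R * _T37 * math.log(n / sizes[-1])
    lo = max(s for s in sizes if s < n)
    hi = min(s for s in sizes if s > n)
    frac = (n - lo) / (hi - lo)
    return _LOOP_DG37[lo] + frac * (_LOOP_DG37[hi] - _LOOP_DG37[lo])


def _nn_key(step: str) -> tuple:
    key = f"{step}/{step.translate(_COMP)}"
    if key in mt.DNA_NN3:
        return mt.DNA_NN3[key]
    rc = reverse_complement(step)
    return mt.DNA_NN3[f"{rc}/{rc.translate(_COMP)}"]


def stem_thermo(
    stem: str,
    temperature: float = 66.0,
    loop_len: int = 30,
    na_mM: float = 50.0,
) -> dict:
    """Unimolecular hairpin stem thermodynamics.

    Sums unified nearest-neighbor dH/dS over the stem duplex, adds
    duplex initiation and terminal corrections, applies the SantaLucia
    entropy salt correction for monovalent cations, and charges the
    hairpin loop penalty (treated as purely entropic).  Returns dH
    (kcal/mol), dS (cal/mol K), dG at ``temperature`` (kcal/mol) and
    the two-state melting temperature in Celsius.
    """
    stem = stem.upper()
    if len(stem) < 2:
        raise ValueError("stem must have at least 2 base pairs")
    dh, ds = mt.DNA_NN3["init"][0], mt.DNA_NN3["init"][1]
    for end in (stem[0], stem[-1]):
        term = "init_A/T" if end in "AT" else "init_G/C"
        dh += mt.DNA_NN3[term][0]
        ds += mt.DNA_NN3[term][1]
    for i in range(len(stem) - 1):
        h, s = _nn_key(stem[i : i + 2])
        dh += h
        ds += s
    ds += 0.368 * (len(stem) - 1) * math.log(na_mM / 1000.0)
    ds_loop = -_loop_dg37(loop_len) * 1000.0 / _T37
    ds_total = ds + ds_loop
    t_kelvin = temperature + 273.15
    dg = dh - t_kelvin * ds_total / 1000.0
    tm = dh * 1000.0 / ds_total - 273.15 if ds_total < 0 else float("inf")
    return {"dH": dh, "dS": ds_total, "dG": dg, "tm": tm}


@dataclass(frozen=True)
class TfpDesign:
    """AP + FR + CRc foldable primer (5' -> 3')."""

    ap: str
    fr: str
    crc: str
    modified_base_count: int = 0

    def __post_init__(self):
        for name in ("ap", "fr", "crc"):
            object.__setattr__(self, name, getattr(self, name).upper())
        if not self.fr:
            raise ValueError("fr must be nonempty")
        if self.modified_base_count > len(self.fr):
            raise ValueError("modified_base_count exceeds FR length")

    @property
    def full_tfp(self) -> str:
        return self.ap + self.fr + self.crc


@dataclass(frozen=True)
class HairpinReport:
    """P2/P3/P4 simulation verdict for one TFP against its template."""

    p2: str
    p3_tm: float
    p3_dG: float
    p4: str | None
    evaluation_temperature: float
    threshold_tm: float
    accepted: bool
    reason: str = "ok"


@dataclass(frozen=True)
class AmpliconDesign:
    tsp: str
    probe: str
    amplicon: str
    length: int
    tm1: float
    tm2: float
    spans: dict  # region name -> (start, end) 0-based half-open on the amplicon


def _max_complementarity(a: str, b: str) -> int:
    """Longest contiguous stretch of `a` whose revcomp occurs in `b`."""
    rc = reverse_complement(a)
    best = 0
    for k in range(min(len(a), len(b)), 0, -1):
        if any(rc[i : i + k] in b for i in range(len(rc) - k + 1)):
            best = k
            break
    return best


def build_tfp(
    p1_template: str,
    ap: str,
    fr: str | None = None,
    fr_length: int = 12,
    crc_length: int = 10,
    modified_bases: int = 8,
    seed: int = 0,
    max_cross_comp: int = 4,
) -> TfpDesign:
    """Assemble a TFP against a P1 template.

    CRc is the reverse complement of the template's first ``crc_length``
    bases, so the primer's 3' end sits on the cut terminus.  The folding
    region is either supplied or generated (seeded, G/C-biased) and is
    rejected if it is complementary to AP or CRc over more than
    ``max_cross_comp`` contiguous bases, which would nucleate spurious
    stems outside the intended FR:FRc pairing.
    """
    p1_template = p1_template.upper()
    ap = ap.upper()
    if crc_length > len(p1_template):
        raise ValueError("p1 template shorter than crc_length")
    if fr is None and fr_length < 6:
        raise ValueError("fr_length must be >= 6")
    crc = reverse_complement(p1_template[:crc_length])

    def _ok(candidate: str) -> bool:
        return (
            _max_complementarity(candidate, ap) <= max_cross_comp
            and _max_complementarity(candidate, crc) <= max_cross_comp
        )

    if fr is not None:
        fr = fr.upper()
        if not _ok(fr):
            raise ValueError("design rejected: FR complementary to AP or CRc beyond threshold")
    else:
        rng = np.random.default_rng(seed)
        for _ in range(500):
            cand = "".join(rng.choice(list("ACGT"), size=fr_length, p=[0.15, 0.35, 0.35, 0.15]))
            if _ok(cand):
                fr = cand
                break
        else:
            raise ValueError("design rejected: no FR without AP/CRc cross-complementarity found")
    return TfpDesign(ap=ap, fr=fr, crc=crc, modified_base_count=modified_bases)


def p2_product(tfp: TfpDesign, p1_template: str, copied_span: int = 24) -> str:
    """Net strand after the linear phase: TFP + target copy + FRc tail.

    The loop-to-be carries the reverse complement of the template
    segment 3' of the capture footprint (where TSP and probe will bind),
    and the strand terminates in FRc because the copy-back round stalls
    at the modified FR/AP junction.
    """
    p1 = p1_template.upper()
    c = len(tfp.crc)
    insert = reverse_complement(p1[c : c + copied_span])
    return tfp.full_tfp + insert + reverse_complement(tfp.fr)


def fold_report(
    tfp: TfpDesign,
    p1_template: str,
    temperature: float = 66.0,
    threshold_tm: float = 66.0,
    copied_span: int = 24,
    na_mM: float = 50.0,
    p2: str | None = None,
) -> HairpinReport:
    """Simulate P2 -> P3 -> P4 and judge stem stability.

    Acceptance is strict: stem Tm must exceed ``threshold_tm`` (equality
    fails) and the folding free energy at ``temperature`` must be
    negative.  A P2 whose 3' tail cannot pair with FR (no FRc) yields no
    hairpin and is rejected outright.  ``p2`` may be supplied to assess
    a mutated or externally built product.
    """
    if p2 is None:
        p2 = p2_product(tfp, p1_template, copied_span=copied_span)
    fr = tfp.fr
    tail = p2[-len(fr):]
    if reverse_complement(tail) != fr:
        return HairpinReport(
            p2=p2, p3_tm=float("nan"), p3_dG=float("nan"), p4=None,
            evaluation_temperature=temperature, threshold_tm=threshold_tm,
            accepted=False, reason="no_stem",
        )
    loop_len = len(p2) - len(tfp.ap) - 2 * len(fr)  # CRc + insert between FR and FRc
    thermo = stem_thermo(fr, temperature=temperature, loop_len=loop_len, na_mM=na_mM)
    # self-priming extension copies the 5' arm upstream of FR, i.e. AP
    p4 = p2 + reverse_complement(tfp.ap)
    accepted = thermo["tm"] > threshold_tm and thermo["dG"] < 0
    return HairpinReport(
        p2=p2, p3_tm=thermo["tm"], p3_dG=thermo["dG"], p4=p4,
        evaluation_temperature=temperature, threshold_tm=threshold_tm,
        accepted=accepted, reason="ok" if accepted else "unstable_stem",
    )


def has_three_prime_overhang(report: HairpinReport) -> bool:
    """Structural check: P4's 3' arm must pair flush with its 5' arm."""
    if report.p4 is None:
        return True
    p4 = report.p4
    arm = len(p4) - len(report.p2)  # length of the appended APc segment
    if arm == 0:
        return False
    return reverse_complement(p4[-arm:]) != p4[:arm]


def amplicon_predict(
    tfp: TfpDesign,
    tsp: str,
    probe: str,
    p1_template: str,
    copied_span: int = 24,
) -> AmpliconDesign:
    """Exponential-phase amplicon delimited by AP and TSP on the hairpin.

    The amplicon read on the TFP strand runs from AP through FR and the
    capture/loop region to the TSP footprint; reported sub-spans tile it
    exactly, and read in reverse-complement order TSP ... probe ... FR
    ... AP, matching the sequenced product structure.  The probe must
    lie strictly between the FR and TSP footprints.
    """
    tsp = tsp.upper()
    probe = probe.upper()
    p2 = p2_product(tfp, p1_template, copied_span=copied_span)
    p4 = p2 + reverse_complement(tfp.ap)
    rc_tsp = reverse_complement(tsp)
    j = p4.find(rc_tsp)
    if j < 0 and tsp in p4:
        j = p4.find(tsp)
        rc_tsp = tsp
    if j < 0:
        raise ValueError("tsp not found in the P4 hairpin")
    amplicon = p4[: j + len(tsp)]
    k = amplicon.find(probe)
    if k < 0:
        k = amplicon.find(reverse_complement(probe))
    if k < 0:
        raise ValueError("probe not found in the predicted amplicon")
    la, lf = len(tfp.ap), len(tfp.fr)
    if not (la + lf <= k and k + len(probe) <= j):
        raise ValueError("probe does not lie strictly between FR and TSP footprints")
    spans = {
        "AP": (0, la),
        "FR": (la, la + lf),
        "pre_probe": (la + lf, k),
        "probe": (k, k + len(probe)),
        "post_probe": (k + len(probe), j),
        "TSP": (j, j + len(tsp)),
    }
    tm1 = float(mt.Tm_NN(tfp.crc, nn_table=mt.DNA_NN3))
    tm2 = float(mt.Tm_NN(tsp, nn_table=mt.DNA_NN3))
    return AmpliconDesign(
        tsp=tsp, probe=probe, amplicon=amplicon, length=len(amplicon),
        tm1=tm1, tm2=tm2, spans=spans,
    )
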