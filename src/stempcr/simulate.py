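"""Synthetic inputs for the whole pipeline.

Three generators emulate the study's data layers without any download:

* two-class beta-value matrices (tumor vs paracancerous tissue) with a
  small set of planted differential CpG sites among many null sites,
  shaped like a 299/298 training array and a 64/64 held-out set;
* methylation-annotated DNA sequences for digestion and primer design;
* stool-cohort qPCR tables (five diagnosis classes, per-marker Ct with a
  nondetect sentinel, and an ACTB reference Ct with a QC-failure
  fraction), shaped like the 429-sample case-control cohort.

Beta noise follows the standard bounded-support model for array betas,
Beta(mean*kappa, (1-mean)*kappa) with concentration kappa.  All
randomness flows from one integer seed per call; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mdre import MethylSequence

__all__ = [
    "EffectProfile",
    "StoolSimSpec",
    "MethylationMatrix",
    "gen_methylation_cohort",
    "gen_methyl_sequence",
    "gen_stool_cohort",
    "DIAGNOSIS_CLASSES",
    "SENTINEL_CT",
]

DIAGNOSIS_CLASSES = ("normal", "CRC", "AA", "polyp", "enteritis")
#: nondetected reactions carry this cycle value (40-cycle program + margin)
SENTINEL_CT = 45.0
CRC_STAGES = ("I", "II", "III", "IV")


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites beta values with labels and site coordinates.

    ``betas`` is a DataFrame (rows = samples, columns = site ids),
    ``labels`` a Series aligned to its rows with exactly two levels for
    mining, and ``coords`` a DataFrame indexed by site id with columns
    ``chrom`` and ``pos`` (1-based).
    """

    betas: pd.DataFrame
    labels: pd.Series
    coords: pd.DataFrame

    def validate(self) -> "MethylationMatrix":
        if self.betas.columns.duplicated().any():
            raise ValueError("duplicate site ids")
        if not self.betas.index.equals(self.labels.index):
            raise ValueError("labels not aligned with samples")
        vals = self.betas.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values outside [0, 1]")
        missing = set(self.betas.columns) - set(self.coords.index)
        if missing:
            raise ValueError(f"sites without coordinates: {sorted(missing)[:5]}")
        return self

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique())

    def subset(self, sites: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.betas[list(sites)], self.labels, self.coords.loc[list(sites)])


@dataclass
class EffectProfile:
    """Planted-effect description of a two-class beta matrix.

    The first ``n_differential`` entries of ``site_ids`` are the
    differential sites (case_mean vs control_mean); the rest are null
    sites at ``null_mean`` in both classes.  ``dispersion`` is the Beta
    concentration kappa (> 0; larger = tighter).  ``coords`` maps site
    id -> (chrom, pos); when omitted, sites are placed on chr1 at 100 bp
    spacing.
    """

    site_ids: Sequence[str]
    n_differential: int
    case_mean: float | Sequence[float] = 0.5
    control_mean: float | Sequence[float] = 0.2
    null_mean: float = 0.15
    dispersion: float = 30.0
    coords: Mapping[str, tuple] | None = None

    def validate(self) -> "EffectProfile":
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids: duplicate identifiers")
        if not 0 <= self.n_differential <= len(self.site_ids):
            raise ValueError("n_differential: exceeds number of sites")
        if self.dispersion <= 0:
            raise ValueError("dispersion: must be > 0")
        for name in ("case_mean", "control_mean"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{name}: beta means must lie in [0, 1]")
            if vals.size not in (1, self.n_differential):
                raise ValueError(f"{name}: expected a scalar or {self.n_differential} values")
        if not 0 <= self.null_mean <= 1:
            raise ValueError("null_mean: beta means must lie in [0, 1]")
        if self.coords is not None:
            seen: dict = {}
            for sid in self.site_ids:
                if sid not in self.coords:
                    raise ValueError(f"coords: missing site {sid}")
                chrom, pos = self.coords[sid]
                if chrom in seen and pos <= seen[chrom]:
                    raise ValueError("coords: positions not strictly increasing within chromosome")
                seen[chrom] = pos
        return self

    def coord_frame(self) -> pd.DataFrame:
        if self.coords is None:
            rows = [("chr1", 1000 + 100 * i) for i in range(len(self.site_ids))]
        else:
            rows = [self.coords[s] for s in self.site_ids]
        return pd.DataFrame(rows, index=list(self.site_ids), columns=["chrom", "pos"])


def _beta_draw(rng: np.random.Generator, mean: float, kappa: float, n: int) -> np.ndarray:
    if mean <= 0.0:
        return np.zeros(n)
    if mean >= 1.0:
        return np.ones(n)
    return rng.beta(mean * kappa, (1.0 - mean) * kappa, size=n)


def gen_methylation_cohort(
    profile: EffectProfile,
    n_case: int,
    n_control: int,
    seed: int,
) -> MethylationMatrix:
    """Draw a labeled two-class beta matrix from a planted-effect profile."""
    profile.validate()
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    sites = list(profile.site_ids)
    case_means = np.broadcast_to(
        np.atleast_1d(np.asarray(profile.case_mean, dtype=float)), (profile.n_differential,)
    )
    control_means = np.broadcast_to(
        np.atleast_1d(np.asarray(profile.control_mean, dtype=float)), (profile.n_differential,)
    )
    cols = {}
    for j, sid in enumerate(sites):
        if j < profile.n_differential:
            mc, mn = case_means[j], control_means[j]
        else:
            mc = mn = profile.null_mean
        cols[sid] = np.concatenate(
            [
                _beta_draw(rng, mc, profile.dispersion, n_case),
                _beta_draw(rng, mn, profile.dispersion, n_control),
            ]
        )
    ids = [f"case_{i:04d}" for i in range(n_case)] + [f"ctrl_{i:04d}" for i in range(n_control)]
    betas = pd.DataFrame(cols, index=ids)
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=ids, name="label")
    return MethylationMatrix(betas, labels, profile.coord_frame()).validate()


def gen_methyl_sequence(
    length: int,
    gc: float = 0.5,
    cpg_positions: Sequence[int] = (),
    methylated: Sequence[int] = (),
    seed: int = 0,
    name: str = "synthetic",
) -> MethylSequence:
    """Random sequence with CG dinucleotides exactly where requested.

    ``cpg_positions`` are 1-based positions of the C of each CpG;
    ``methylated`` (a subset) marks symmetric methylation.  Accidental
    CG dinucleotides arising from the random background are removed, so
    downstream digestion sees only the configured dyads.
    """
    cpg = sorted(int(p) for p in cpg_positions)
    meth = sorted(int(p) for p in methylated)
    if not set(meth) <= set(cpg):
        raise ValueError("methylated positions must be a subset of cpg_positions")
    for p in cpg:
        if not 1 <= p <= length - 1:
            raise ValueError(f"CpG position {p} outside [1, {length - 1}]")
    for a, b in zip(cpg, cpg[1:]):
        if b - a < 2:
            raise ValueError(f"overlapping CpG positions {a} and {b}")
    if not 0 <= gc <= 1:
        raise ValueError("gc fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list("ACGT"), size=length, p=probs))
    for p in cpg:
        seq[p - 1] = "C"
        seq[p] = "G"
    requested = set(cpg)
    for i in range(1, length):  # 1-based scan for accidental CGs
        if seq[i - 1] == "C" and seq[i] == "G" and i not in requested:
            seq[i - 1] = "A" if rng.random() < 0.5 else "T"
    return MethylSequence(name, "".join(seq), frozenset(meth))


def _default_detect_prob() -> dict:
    # per-class positivity emulating the two headline stool markers
    return {
        "SDC2-6": {"CRC": 0.912, "normal": 0.043, "AA": 0.581, "polyp": 0.12, "enteritis": 0.12},
        "SFRP2-1": {"CRC": 0.859, "normal": 0.043, "AA": 0.419, "polyp": 0.10, "enteritis": 0.10},
    }


@dataclass
class StoolSimSpec:
    """Configuration of a synthetic stool-cohort qPCR table.

    Defaults emulate the full 429-sample case-control cohort: class
    sizes 161 normal / 205 CRC / 31 AA / 18 polyp / 14 enteritis,
    detection probabilities taken from the per-class positivity rates of
    the two headline markers, detected Ct ~ Normal(30, 2) cycles, a
    nondetect sentinel of 45 cycles, ACTB Ct ~ Normal(20, 1.5), and a
    7.7% fraction of samples failing the ACTB > 24.5 sufficiency rule.
    """

    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 161, "CRC": 205, "AA": 31, "polyp": 18, "enteritis": 14}
    )
    detect_prob: Mapping[str, Mapping[str, float]] = field(default_factory=_default_detect_prob)
    ct_mean: float = 30.0
    ct_sd: float = 2.0
    sentinel_ct: float = SENTINEL_CT
    actb_mean: float = 20.0
    actb_sd: float = 1.5
    qc_fail_fraction: float = 36 / 465
    qc_cutoff: float = 24.5
    seed: int = 0

    def validate(self) -> "StoolSimSpec":
        if not self.class_sizes:
            raise ValueError("class_sizes: empty")
        for cls, n in self.class_sizes.items():
            if cls not in DIAGNOSIS_CLASSES:
                raise ValueError(f"class_sizes: unknown class {cls!r}")
            if n < 0:
                raise ValueError("class_sizes: sizes must be >= 0")
        for marker, per_class in self.detect_prob.items():
            for cls, p in per_class.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"detect_prob[{marker}][{cls}]: not in [0, 1]")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction: not in [0, 1]")
        if self.sentinel_ct <= self.ct_mean + 6 * self.ct_sd:
            raise ValueError("sentinel_ct: must exceed any achievable detected Ct")
        return self

    @property
    def markers(self) -> list:
        return list(self.detect_prob)


def gen_stool_cohort(spec: StoolSimSpec) -> pd.DataFrame:
    """One row per sample: class, stage, per-marker Ct, ACTB Ct.

    Detected reactions draw Ct from the configured normal distribution;
    nondetects carry the sentinel.  Realized class counts equal
    ``class_sizes`` exactly; QC failures are per-sample Bernoulli draws
    pushed above the ACTB cutoff.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cls, n in spec.class_sizes.items():
        for i in range(n):
            stage = rng.choice(CRC_STAGES) if cls == "CRC" else ""
            row = {"sample_id": f"{cls}_{i:04d}", "class": cls, "stage": stage}
            for marker in spec.markers:
                p = spec.detect_prob[marker].get(cls, 0.0)
                if rng.random() < p:
                    ct = rng.normal(spec.ct_mean, spec.ct_sd)
                    ct = float(np.clip(ct, 1.0, spec.sentinel_ct - 1.0))
                else:
                    ct = spec.sentinel_ct
                row[marker] = ct
            if rng.random() < spec.qc_fail_fraction:
                actb = spec.qc_cutoff + 0.1 + abs(rng.normal(1.5, 1.0))
            else:
                actb = rng.normal(spec.actb_mean, spec.actb_sd)
                while actb > spec.qc_cutoff or actb <= 0:
                    actb = rng.normal(spec.actb_mean, spec.actb_sd)
            row["ACTB_Ct"] = float(actb)
            rows.append(row)
    cols = ["sample_id", "class", "stage", *spec.markers, "ACTB_Ct"]
    return pd.DataFrame(rows, columns=cols)
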