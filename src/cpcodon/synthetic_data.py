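"""Synthetic coding-sequence generators with controlled usage structure.

Two generators cover the pipeline's needs:

* :func:`generate_genome` draws a set of structurally valid CDS (ATG
  start, clean stop, no internal stop, length a multiple of 3 and
  >= 300 bp) from a :class:`UsageProfile` controlling within-family
  codon probabilities, a per-gene GC3 target range, and an optional
  Dirichlet concentration that skews families from uniform (ENC near
  61) down to near-degenerate usage (ENC near 20).
* :func:`generate_neutrality_set` plants a linear GC12-on-GC3
  relationship by mixing amino acids whose first two codon positions
  are all-GC (Ala, Gly, Pro) or GC-free (Lys, Phe, Asn, Tyr) in a
  proportion tracking the per-gene target, so regression-recovery of a
  known slope can be tested.

Every draw comes from a single seeded ``numpy`` generator, so output is
byte-identical for a given parameter set and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cds_io import CdsRecord
from .genetic_code import AA_TO_CODONS, SENSE_FAMILIES

#: Amino acids whose codons have GC at both of the first two positions.
_HIGH_GC12_AA = ("A", "G", "P")
#: Amino acids whose codons have A/T at both of the first two positions,
#: with third-position degeneracy so GC3 stays controllable.
_LOW_GC12_AA = ("K", "F", "N", "Y")

_SENSE_AAS = tuple(sorted(SENSE_FAMILIES))


@dataclass
class UsageProfile:
    """Parameters of a synthetic CDS set.

    Parameters
    ----------
    codon_probs : per-amino-acid codon probability vectors (keys "A".."Y"
        plus "*" for the stop family); families omitted default to
        uniform. Each family must sum to 1.
    aa_weights : relative usage of the 20 sense amino acids for internal
        codons; default uniform.
    gene_count, length_range : number of genes and the inclusive bp
        range from which (triplet) gene lengths are drawn; the minimum
        must be >= 300 and divisible by 3.
    gc3_gradient : optional (low, high) interval of per-gene GC3
        targets; within each family, codon probabilities are reweighted
        toward G/C- or A/T-ending members to meet the gene's target.
    bias_concentration : optional symmetric Dirichlet concentration;
        when set, each family's probabilities are redrawn once per
        genome (small values concentrate usage, large values approach
        uniform).
    seed : integer seed; the generator is fully deterministic given it.
    """

    codon_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    aa_weights: dict[str, float] = field(default_factory=dict)
    gene_count: int = 50
    length_range: tuple[int, int] = (300, 1602)
    gc3_gradient: tuple[float, float] | None = None
    bias_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 300 or lo % 3 or hi < lo:
            raise ValueError("length_range minimum must be >= 300, divisible by 3")
        for aa, probs in self.codon_probs.items():
            if aa not in AA_TO_CODONS:
                raise ValueError(f"unknown amino acid {aa!r}")
            if set(probs) != set(AA_TO_CODONS[aa]):
                raise ValueError(f"family {aa}: probabilities must cover all codons")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"family {aa}: probabilities must sum to 1")
        if self.gc3_gradient is not None:
            lo_g, hi_g = self.gc3_gradient
            if not (0.0 < lo_g <= hi_g < 1.0):
                raise ValueError("gc3_gradient must lie strictly inside (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "codon_probs": self.codon_probs,
            "aa_weights": self.aa_weights,
            "gene_count": self.gene_count,
            "length_range": list(self.length_range),
            "gc3_gradient": list(self.gc3_gradient) if self.gc3_gradient else None,
            "bias_concentration": self.bias_concentration,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "UsageProfile":
        raw = json.loads(Path(path).read_text())
        raw["length_range"] = tuple(raw["length_range"])
        if raw.get("gc3_gradient"):
            raw["gc3_gradient"] = tuple(raw["gc3_gradient"])
        return cls(**raw)


def _family_probs(profile: UsageProfile, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Resolve per-family codon probabilities for one genome draw."""
    probs: dict[str, np.ndarray] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in profile.codon_probs:
            p = np.array([profile.codon_probs[aa][c] for c in codons])
        elif profile.bias_concentration is not None and len(codons) > 1:
            p = rng.dirichlet([profile.bias_concentration] * len(codons))
        else:
            p = np.full(len(codons), 1.0 / len(codons))
        probs[aa] = p
    return probs


def _gc3_reweight(codons: Sequence[str], p: np.ndarray, target: float) -> np.ndarray:
    """Tilt family probabilities so the expected third-position GC is near target."""
    gc_end = np.array([c[2] in "GC" for c in codons], dtype=float)
    if gc_end.all() or not gc_end.any():
        return p
    w = p * np.where(gc_end == 1.0, target, 1.0 - target)
    return w / w.sum()


def generate_genome(profile: UsageProfile) -> list[CdsRecord]:
    """Draw a synthetic CDS set; every gene passes the structural screen."""
    rng = np.random.default_rng(profile.seed)
    base_probs = _family_probs(profile, rng)
    aas = _SENSE_AAS
    aa_w = np.array([profile.aa_weights.get(aa, 1.0) for aa in aas], dtype=float)
    aa_w = aa_w / aa_w.sum()
    lo, hi = profile.length_range
    codon_counts = np.arange(lo // 3, hi // 3 + 1)
    stop_codons = AA_TO_CODONS["*"]

    records: list[CdsRecord] = []
    for i in range(profile.gene_count):
        n_codons = int(rng.choice(codon_counts))
        if profile.gc3_gradient is not None:
            g3 = float(rng.uniform(*profile.gc3_gradient))
            probs = {
                aa: _gc3_reweight(AA_TO_CODONS[aa], base_probs[aa], g3)
                for aa in AA_TO_CODONS
            }
        else:
            probs = base_probs
        internal_aas = rng.choice(len(aas), size=n_codons - 2, p=aa_w)
        body = [
            AA_TO_CODONS[aas[j]][rng.choice(len(probs[aas[j]]), p=probs[aas[j]])]
            for j in internal_aas
        ]
        stop = stop_codons[rng.choice(len(stop_codons), p=probs["*"])]
        seq = "ATG" + "".join(body) + stop
        records.append(CdsRecord(f"synth_{i:04d}", "synthetic", seq))
    return records


def generate_neutrality_set(
    slope: float,
    intercept: float,
    noise_sd: float = 0.01,
    gene_count: int = 60,
    seed: int = 0,
    gc3_range: tuple[float, float] = (0.15, 0.60),
    gene_length: int = 1200,
) -> list[CdsRecord]:
    """Genes with a planted linear GC12-on-GC3 relationship.

    Per gene, a GC3 target is drawn uniformly on ``gc3_range`` and the
    GC12 target is ``slope * GC3 + intercept + N(0, noise_sd)``. The
    GC12 target must stay within (0, 1) over the whole range.
    """
    lo, hi = gc3_range
    for g3 in (lo, hi):
        t = slope * g3 + intercept
        if not 0.0 < t < 1.0:
            raise ValueError(
                f"GC12 target {t:.3f} at GC3={g3} falls outside (0, 1)"
            )
    if gene_length < 300 or gene_length % 3:
        raise ValueError("gene_length must be >= 300 and divisible by 3")
    rng = np.random.default_rng(seed)
    n_internal = gene_length // 3 - 2
    stop_codons = AA_TO_CODONS["*"]
    records: list[CdsRecord] = []
    for i in range(gene_count):
        g3 = float(rng.uniform(lo, hi))
        t12 = float(np.clip(slope * g3 + intercept + rng.normal(0.0, noise_sd), 0.01, 0.99))
        body = []
        for _ in range(n_internal):
            pool = _HIGH_GC12_AA if rng.random() < t12 else _LOW_GC12_AA
            aa = pool[rng.choice(len(pool))]
            codons = AA_TO_CODONS[aa]
            p = _gc3_reweight(codons, np.full(len(codons), 1.0 / len(codons)), g3)
            body.append(codons[rng.choice(len(codons), p=p)])
        stop = stop_codons[rng.choice(len(stop_codons))]
        records.append(CdsRecord(f"neut_{i:04d}", "synthetic", "ATG" + "".join(body) + stop))
    return records


def write_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    """Write CDS records as uncompressed FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
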