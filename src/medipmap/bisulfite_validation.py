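"""Bisulfite-clone validation of MeDIP methylation calls.

Models the chemistry and the read-out: bisulfite converts every
unmethylated C to T while methylated CpG cytosines stay C; sequenced
clones are globally aligned to the in-silico converted reference and the
base observed at each reference CpG site yields the per-clone call
(C = methylated, T = unmethylated, anything else = NA). A region's
clone matrix is then compared qualitatively with MeDIP peaks: a peak
should coincide with high bisulfite methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

LOW_METHYLATION_THRESHOLD = 0.2


@dataclass
class AmpliconRegion:
    name: str
    chrom: str
    start_1based: int
    end_1based: int
    expected_class: str | None = None  # "low" or "high"

    def __post_init__(self) -> None:
        if self.start_1based > self.end_1based:
            raise ValueError(f"{self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end_1based - self.start_1based + 1

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open internal coordinates."""
        return self.start_1based - 1, self.end_1based


def amplicon_from_coords(
    name: str, chrom: str, start_1based: int, end_1based: int, expected_class=None
) -> AmpliconRegion:
    """Build an amplicon from printed 1-based inclusive coordinates."""
    return AmpliconRegion(name, chrom, start_1based, end_1based, expected_class)


def cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CpG in ``seq``."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def bisulfite_convert(seq: str, methylated_cpg_positions: Iterable[int] = ()) -> str:
    """Convert every C outside the protected CpG set to T.

    ``methylated_cpg_positions`` must be C positions in CpG context.
    """
    seq = seq.upper()
    protected = set(methylated_cpg_positions)
    sites = set(cpg_sites(seq))
    bad = protected - sites
    if bad:
        raise ValueError(f"protected positions not CpG-context cytosines: {sorted(bad)}")
    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in protected:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def call_clone_methylation(
    clone_seq: str, reference_region_seq: str, min_identity: float = 0.9
) -> list[float]:
    """Per-CpG calls for one clone: 1.0 methylated, 0.0 unmethylated, nan NA.

    The clone is globally aligned (match +1, mismatch -1, gap -2) to the
    reference with all non-CpG cytosines converted; C/T status at each
    reference CpG gives the call. Identity is gated at ``min_identity``
    over non-CpG reference positions; failing clones raise ValueError.
    """
    ref = reference_region_seq.upper()
    sites = cpg_sites(ref)
    # conversion target: non-CpG C -> T, CpG C kept (clone may show C or T there)
    ref_conv = bisulfite_convert(ref, sites)
    aln = _aligner().align(ref_conv, clone_seq.upper())[0]
    site_set = set(sites)
    ref2clone: dict[int, str] = {}
    matches = comparable = 0
    for (rs, re_), (qs, _qe) in zip(*aln.aligned):
        for off in range(re_ - rs):
            ri, qi = rs + off, qs + off
            ref2clone[ri] = aln.query[qi]
            if ri not in site_set:
                comparable += 1
                matches += aln.query[qi] == ref_conv[ri]
    if comparable == 0 or matches / comparable < min_identity:
        raise ValueError(
            f"clone identity {matches}/{comparable} below {min_identity:.0%}; clone rejected"
        )
    calls: list[float] = []
    for s in sites:
        base = ref2clone.get(s)
        if base == "C":
            calls.append(1.0)
        elif base == "T":
            calls.append(0.0)
        else:
            calls.append(float("nan"))
    return calls


@dataclass
class CloneMethylationMatrix:
    region: AmpliconRegion
    matrix: np.ndarray  # clones x CpG sites; 1/0/nan
    site_positions: list[int]

    @property
    def per_site_fraction(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)

    @property
    def per_clone_fraction(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=1)

    @property
    def mean_fraction(self) -> float:
        return float(np.nanmean(self.matrix))

    def lollipop(self) -> str:
        """ASCII clone diagram: ● methylated, ○ unmethylated, · no call."""
        rows = []
        for clone in self.matrix:
            rows.append(
                "".join("●" if v == 1 else "○" if v == 0 else "·" for v in clone)
            )
        return "\n".join(rows)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("clone\t" + "\t".join(f"cpg_{p}" for p in self.site_positions) + "\n")
            for i, clone in enumerate(self.matrix, 1):
                vals = ["NA" if np.isnan(v) else str(int(v)) for v in clone]
                fh.write(f"clone_{i}\t" + "\t".join(vals) + "\n")


def build_clone_matrix(
    region: AmpliconRegion, clone_seqs: Sequence[str], reference_region_seq: str,
    min_identity: float = 0.9,
) -> CloneMethylationMatrix:
    sites = cpg_sites(reference_region_seq.upper())
    rows = []
    for seq in clone_seqs:
        try:
            rows.append(call_clone_methylation(seq, reference_region_seq, min_identity))
        except ValueError:
            continue  # rejected clone; noticed by caller via matrix height
    if not rows:
        raise ValueError(f"{region.name}: no clone passed the identity gate")
    return CloneMethylationMatrix(region, np.array(rows, dtype=float), sites)


def simulate_clones(
    reference_region_seq: str,
    per_site_methylation: Sequence[float] | float,
    n_clones: int,
    rng: np.random.Generator,
    conversion_failure_rate: float = 0.01,
    inappropriate_conversion_rate: float = 0.01,
) -> list[str]:
    """Simulate bisulfite-converted clone sequences from a methylation vector.

    Each clone draws the methylation state of each CpG independently; the
    error model keeps an unmethylated C with ``conversion_failure_rate``
    and converts a methylated C with ``inappropriate_conversion_rate``.
    """
    ref = reference_region_seq.upper()
    sites = cpg_sites(ref)
    probs = (
        np.full(len(sites), per_site_methylation, dtype=float)
        if np.isscalar(per_site_methylation)
        else np.asarray(per_site_methylation, dtype=float)
    )
    if probs.shape != (len(sites),):
        raise ValueError("methylation vector length must equal the number of CpG sites")
    clones = []
    for _ in range(n_clones):
        meth = rng.random(len(sites)) < probs
        fail = rng.random(len(sites)) < conversion_failure_rate
        inapp = rng.random(len(sites)) < inappropriate_conversion_rate
        observed_c = np.where(meth, ~inapp, fail)
        protected = {s for s, keep in zip(sites, observed_c) if keep}
        clones.append(bisulfite_convert(ref, protected))
    return clones


def concordance_report(
    matrix: CloneMethylationMatrix,
    medip_peaks,
    region: AmpliconRegion,
    low_threshold: float = LOW_METHYLATION_THRESHOLD,
) -> str:
    """"agree" when peak presence coincides with high bisulfite methylation."""
    if matrix.matrix.size == 0:
        raise ValueError("empty clone matrix")
    s, e = region.interval
    has_peak = any(
        p.chrom == region.chrom and p.start < e and s < p.end for p in medip_peaks
    )
    high = matrix.mean_fraction >= low_threshold
    return "agree" if has_peak == high else "disagree"
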