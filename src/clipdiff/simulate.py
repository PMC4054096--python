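"""Synthetic CLIP-seq inputs with known ground truth.

Two levels of generator back the test surface:

* :func:`simulate_bin_sequences` draws per-cluster adjusted-M sequences
  directly from the HMM + mixture generative model (Markov states, normal
  emissions), returning the true state paths for recovery checks.
* :func:`simulate_sam_pair` writes a pair of miniature SAM files over a
  toy two-contig genome, with planted common and differential binding
  regions at configurable intensity ratios and protocol-specific
  characteristic mutations (deletions for HITS-CLIP, T->C conversions for
  PAR-CLIP, barcoded truncation-site FASTQ for iCLIP), plus a truth BED
  and a JSON manifest.

Everything is driven by one :class:`numpy.random.Generator` seeded from
the scenario, so identical scenarios produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mixture import MixtureParams

PROTOCOLS = ("HITS-CLIP", "PAR-CLIP", "iCLIP")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_scenario_transitions() -> np.ndarray:
    """Persistent chain with diagonal (0.80, 0.95, 0.80): differential
    stretches are short relative to the common background."""
    return np.array([
        [0.80, 0.10, 0.10],
        [0.025, 0.95, 0.025],
        [0.10, 0.10, 0.80],
    ])


def default_scenario_mixture() -> MixtureParams:
    return MixtureParams(p=0.15, mu=1.5, sigma=0.8)


@dataclass
class SimulationScenario:
    """Study conditions for both generator levels.

    Bin-level fields: ``n_clusters`` sequences of ``bins_per_cluster``
    steps from ``transitions`` (uniform initial state) with M values from
    the ``mixture`` component of the current state.

    Read-level fields: ``n_regions`` planted regions of
    ``region_length`` bp, a ``common_fraction_target`` share of them
    common and the rest split between stronger-in-condition-1 and
    stronger-in-condition-2; ``reads_per_region`` expected tags per region
    per condition at baseline, multiplied by ``intensity_ratio`` in the
    favoured condition of a differential region and by ``depth_ratio``
    globally in condition 2 (pure sequencing-depth imbalance, which the
    normalization must remove); ``mutation_rate`` is the per-tag chance of
    a characteristic mutation at the region's planted crosslink site.
    """

    seed: int = 0
    # bin-level generator
    n_clusters: int = 500
    bins_per_cluster: int | tuple[int, int] = 50
    transitions: np.ndarray = field(default_factory=default_scenario_transitions)
    mixture: MixtureParams = field(default_factory=default_scenario_mixture)
    # read-level generator
    protocol: str = "HITS-CLIP"
    common_fraction_target: float = 0.7
    depth_ratio: float = 1.0
    intensity_ratio: float = 4.0
    mutation_rate: float = 0.2
    duplication_rate: float = 0.1
    n_regions: int = 60
    region_length: int = 400
    region_gap: int = 300
    reads_per_region: int = 100
    read_length: int = 36
    read_length_jitter: int = 5
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000})
    iclip_barcode_length: int = 5

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if not 0 < self.common_fraction_target < 1:
            raise ValueError("common_fraction_target must be in (0, 1)")
        if self.depth_ratio <= 0 or self.intensity_ratio <= 0:
            raise ValueError("depth_ratio and intensity_ratio must be > 0")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_mixture(n: int, params: MixtureParams, rng: np.random.Generator) -> np.ndarray:
    """n independent draws from the three-component emission mixture."""
    comp = rng.choice(3, size=n, p=[params.p, 1 - 2 * params.p, params.p])
    means = params.means[comp]
    return rng.normal(means, params.sigma)


def simulate_bin_sequences(
    scenario: SimulationScenario,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Draw per-cluster M-value sequences from the generative model.

    Returns (M sequences, true state paths); states follow the scenario's
    Markov chain from a uniform initial state, and each M value is normal
    around the mean of its state's component.
    """
    rng = scenario.rng()
    pi = np.asarray(scenario.transitions, dtype=float)
    mix = scenario.mixture
    if isinstance(scenario.bins_per_cluster, tuple):
        lo, hi = scenario.bins_per_cluster
        lengths = rng.integers(lo, hi + 1, size=scenario.n_clusters)
    else:
        lengths = np.full(scenario.n_clusters, scenario.bins_per_cluster)
    seqs, paths = [], []
    for L in lengths:
        states = np.empty(int(L), dtype=np.int64)
        states[0] = rng.choice(3)
        for t in range(1, int(L)):
            states[t] = rng.choice(3, p=pi[states[t - 1]])
        m = rng.normal(mix.means[states], mix.sigma)
        seqs.append(m)
        paths.append(states)
    return seqs, paths


def _plan_regions(scenario: SimulationScenario, rng: np.random.Generator):
    """Lay out planted regions on the toy genome and assign states.

    Regions are tiled with ``region_gap`` spacing (larger than a read, so
    every region becomes its own cluster); states are a shuffled mix
    honouring ``common_fraction_target``; strands alternate.
    """
    n = scenario.n_regions
    n_common = int(round(n * scenario.common_fraction_target))
    n_up = (n - n_common + 1) // 2
    n_down = n - n_common - n_up
    states = np.array([1] * n_common + [0] * n_up + [2] * n_down)
    rng.shuffle(states)
    regions = []
    i = 0
    step = scenario.region_length + scenario.region_gap
    for chrom, length in scenario.contig_lengths.items():
        pos = 1000
        while pos + scenario.region_length + 1000 < length and i < n:
            strand = "+" if i % 2 == 0 else "-"
            regions.append({
                "chrom": chrom,
                "start": pos,
                "end": pos + scenario.region_length,
                "state": int(states[i]),
                "strand": strand,
                "crosslink": pos + scenario.region_length // 2,
            })
            pos += step
            i += 1
    if i < n:
        raise ValueError("toy genome too small for the requested regions")
    return regions


def _reference(scenario: SimulationScenario, regions, rng: np.random.Generator
               ) -> dict[str, np.ndarray]:
    """Uniform random reference; crosslink bases forced to the PAR-CLIP
    photoactivatable base (T on +, its complement A on -)."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref = {c: bases[rng.integers(0, 4, size=n)].copy()
           for c, n in scenario.contig_lengths.items()}
    for r in regions:
        ref[r["chrom"]][r["crosslink"]] = ord("T") if r["strand"] == "+" else ord("A")
    return ref


def _sam_header(scenario: SimulationScenario) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in scenario.contig_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    return "\n".join(lines) + "\n"


def _make_read(ref: np.ndarray, chrom: str, start: int, L: int, strand: str,
               mutate: str | None, cpos: int, name: str) -> str:
    """One SAM line; ``mutate`` is None, 'deletion' or 'substitution' at
    reference position ``cpos`` (which must fall inside the read)."""
    flag = 0 if strand == "+" else 16
    off = cpos - start
    if mutate == "deletion":
        seq = (ref[start:start + off].tobytes()
               + ref[start + off + 1:start + L + 1].tobytes()).decode()
        cigar = f"{off}M1D{L - off}M"
        md = f"{off}^{chr(ref[cpos])}{L - off}"
    elif mutate == "substitution":
        refbase = chr(ref[cpos])
        alt = "C" if refbase == "T" else "G"  # T->C on +, A->G on -
        s = bytearray(ref[start:start + L].tobytes())
        s[off] = ord(alt)
        seq = s.decode()
        cigar = f"{L}M"
        md = f"{off}{refbase}{L - 1 - off}"
    else:
        seq = ref[start:start + L].tobytes().decode()
        cigar = f"{L}M"
        md = str(L)
    return (f"{name}\t{flag}\t{chrom}\t{start + 1}\t255\t{cigar}\t*\t0\t0\t"
            f"{seq}\t{'I' * len(seq)}\tMD:Z:{md}\n")


def simulate_sam_pair(scenario: SimulationScenario, out_dir: str) -> dict:
    """Write cond1.sam / cond2.sam, truth.bed and manifest.json.

    Read counts per region and condition are Poisson around the planted
    expectations; read starts are uniform within the region. A
    ``duplication_rate`` share of reads is emitted twice to exercise PCR
    duplicate collapsing. iCLIP scenarios additionally write
    cond{1,2}.fastq with 5' random barcodes and planted FASTQ-level PCR
    duplicates. Returns the manifest (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = scenario.rng()
    regions = _plan_regions(scenario, rng)
    ref = _reference(scenario, regions, rng)
    L = scenario.read_length
    protocol = scenario.protocol
    mut_kind = {"HITS-CLIP": "deletion", "PAR-CLIP": "substitution",
                "iCLIP": None}[protocol]
    sam_paths = {1: out / "cond1.sam", 2: out / "cond2.sam"}
    handles = {c: open(p, "w") for c, p in sam_paths.items()}
    for h in handles.values():
        h.write(_sam_header(scenario))
    counter = 0
    for r in regions:
        chrom, strand, cpos = r["chrom"], r["strand"], r["crosslink"]
        refseq = ref[chrom]
        for cond in (1, 2):
            mean = scenario.reads_per_region
            if (r["state"] == 0 and cond == 1) or (r["state"] == 2 and cond == 2):
                mean *= scenario.intensity_ratio
            if cond == 2:
                mean *= scenario.depth_ratio
            n_reads = int(rng.poisson(mean))
            jit = scenario.read_length_jitter
            max_len = L + jit
            starts = rng.integers(r["start"], r["end"] - max_len - 1, size=n_reads)
            lengths = rng.integers(L - jit, L + jit + 1, size=n_reads)
            order = np.argsort(starts, kind="stable")
            for s, rl in zip(starts[order], lengths[order]):
                s, rl = int(s), int(rl)
                mutate = None
                if (mut_kind is not None and s + 1 <= cpos <= s + rl - 2
                        and rng.random() < scenario.mutation_rate):
                    mutate = mut_kind
                line = _make_read(refseq, chrom, s, rl, strand, mutate, cpos,
                                  f"r{cond}_{counter}")
                counter += 1
                handles[cond].write(line)
                if rng.random() < scenario.duplication_rate:
                    handles[cond].write(line)  # PCR duplicate, same name on purpose
    for h in handles.values():
        h.close()
    truth_path = out / "truth.bed"
    with open(truth_path, "w") as bed:
        for r in regions:
            bed.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                      f"state{r['state']}\t0\t{r['strand']}\n")
    manifest = {
        "scenario": {
            k: v for k, v in dataclasses.asdict(scenario).items()
            if not isinstance(v, (np.ndarray, MixtureParams, dict))
        },
        "protocol": protocol,
        "n_regions": len(regions),
        "regions": regions,
        "files": {"cond1": "cond1.sam", "cond2": "cond2.sam",
                  "truth_bed": "truth.bed"},
    }
    if protocol == "iCLIP":
        manifest["files"].update(_write_iclip_fastq(scenario, regions, ref, out, rng))
    # JSON keeps paths relative to out_dir so identical scenarios produce
    # byte-identical directories wherever they are written
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest["files"] = {k: str(out / v) for k, v in manifest["files"].items()}
    return manifest


def _write_iclip_fastq(scenario: SimulationScenario, regions, ref, out: Path,
                       rng: np.random.Generator) -> dict[str, str]:
    """Raw iCLIP FASTQ: random 5' barcodes on region-derived inserts, with
    exact PCR duplicates planted at ``duplication_rate``."""
    L = scenario.read_length
    bl = scenario.iclip_barcode_length
    bases = "ACGT"
    paths = {}
    for cond in (1, 2):
        path = out / f"cond{cond}.fastq"
        with open(path, "w") as fq:
            i = 0
            for r in regions:
                n_reads = max(1, int(scenario.reads_per_region // 4))
                starts = rng.integers(r["start"], r["end"] - L - 1, size=n_reads)
                for s in np.sort(starts):
                    barcode = "".join(bases[b] for b in rng.integers(0, 4, size=bl))
                    insert = ref[r["chrom"]][int(s):int(s) + L].tobytes().decode()
                    seq = barcode + insert
                    reps = 1 + (1 if rng.random() < scenario.duplication_rate else 0)
                    for _ in range(reps):
                        fq.write(f"@icl{cond}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                        i += 1
        paths[f"fastq{cond}"] = path.name
    return paths
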