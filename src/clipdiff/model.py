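"""Model/Results interface for differential CLIP-seq comparison.

:class:`ClipDifferentialModel` holds the binned data for one two-condition
comparison (built directly from bin/cluster frames or via
:meth:`ClipDifferentialModel.from_sam` from a pair of alignment files) and
its :meth:`~ClipDifferentialModel.fit` runs the full statistical
procedure — MA normalization, robust mixture estimation, transition
training and Viterbi decoding — returning a
:class:`ClipDifferentialResults` with the estimates, diagnostics, decoded
states, merged state regions and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import clusters as _clusters
from . import hmm as _hmm
from . import iclip as _iclip
from . import mixture as _mixture
from . import normalization as _norm
from . import reporting as _reporting
from .clusters import BinningConfig, Tracks
from .ingest import IngestConfig, collapse_duplicates, read_alignments
from .mixture import STATE_NAMES
from .normalization import NormalizationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the documented defaults."""

    protocol: str = "HITS-CLIP"
    mutation_type: str = "none"
    paired_end: bool = False
    min_mapping_quality: int = 0
    bin_size: int = 5
    min_cluster_tags: int = 10
    expansion_width: int = 2
    pseudocount_c: float = 1.0
    joint_count_cutoff: int = 5
    hmm_max_iterations: int = 100
    hmm_tolerance: float = 1e-4

    def binning(self) -> BinningConfig:
        return BinningConfig(self.bin_size, self.min_cluster_tags)

    def normalization(self) -> NormalizationConfig:
        return NormalizationConfig(self.pseudocount_c, self.joint_count_cutoff)

    def ingest(self) -> IngestConfig:
        return IngestConfig(self.mutation_type, self.paired_end,
                            self.min_mapping_quality)

    def stop(self) -> _hmm.HMMStopConfig:
        return _hmm.HMMStopConfig(self.hmm_max_iterations, self.hmm_tolerance)


class ClipDifferentialModel:
    """Two-condition differential binding model over binned CLIP clusters.

    Parameters
    ----------
    bins : DataFrame with the cluster/bin geometry and per-bin counts
        (columns of :data:`clipdiff.clusters.BIN_COLUMNS`).
    clusters : DataFrame of called clusters.
    config : PipelineConfig, optional.
    total_tracks, mutant_tracks : per-base count tracks kept for the
        bedGraph outputs; optional when only estimates are wanted.
    """

    def __init__(
        self,
        bins: pd.DataFrame,
        clusters: pd.DataFrame,
        config: Optional[PipelineConfig] = None,
        total_tracks: Optional[Tracks] = None,
        mutant_tracks: Optional[Tracks] = None,
    ) -> None:
        if len(bins) == 0:
            raise ValueError("no bins: no clusters survived filtering")
        self.bins = bins.sort_values(["cluster_id", "bin_index"]).reset_index(drop=True)
        self.clusters = clusters
        self.config = config or PipelineConfig()
        self.total_tracks = total_tracks or {}
        self.mutant_tracks = mutant_tracks or {}

    # ------------------------------------------------------------------
    @classmethod
    def from_sam(
        cls,
        sam1: str,
        sam2: str,
        config: Optional[PipelineConfig] = None,
    ) -> "ClipDifferentialModel":
        """Build the model from one SAM file per condition.

        HITS-CLIP/PAR-CLIP: tags are duplicate-collapsed and coverage is
        base-wise tag coverage. iCLIP: inputs must already be mapped,
        barcode-deduplicated cDNAs (see :func:`clipdiff.iclip.remove_barcodes`);
        coverage is the expanded crosslink-nucleotide count track and
        mutant counts are all zero.
        """
        config = config or PipelineConfig()
        ingest_cfg = config.ingest()
        tags = []
        for cond, path in ((1, sam1), (2, sam2)):
            raw = list(read_alignments(path, cond, ingest_cfg))
            if config.protocol == "iCLIP":
                tags.extend(raw)  # deduplicated pre-mapping by barcode
            else:
                tags.extend(collapse_duplicates(raw))
            logger.info("condition %d: %d records -> %d tags", cond, len(raw),
                        len(tags))
        if config.protocol == "iCLIP":
            coverage = _iclip.expand_crosslink_sites(
                tags, _iclip.CrosslinkConfig(config.expansion_width))
            counts = _iclip.crosslink_event_tracks(tags)
            mut_tracks: Tracks = {}
        else:
            coverage = _clusters.build_coverage(tags)
            counts = _clusters.tag_start_tracks(tags)
            mut_tracks = _clusters.mutation_tracks(tags)
        binning = config.binning()
        cluster_df = _clusters.call_clusters(coverage, binning, counts)
        bins = _clusters.bin_clusters(cluster_df, coverage, mut_tracks, binning)
        return cls(bins, cluster_df, config, total_tracks=coverage,
                   mutant_tracks=mut_tracks)

    # ------------------------------------------------------------------
    def sequences(self, column: str = "M_adj") -> list[np.ndarray]:
        """Per-cluster value sequences in (cluster_id, bin_index) order."""
        return [grp[column].to_numpy()
                for _, grp in self.bins.groupby("cluster_id", sort=True)]

    def fit(self, stop: Optional[_hmm.HMMStopConfig] = None) -> "ClipDifferentialResults":
        """Run normalization, mixture estimation, HMM training and decoding."""
        cfg = self.config
        bins, norm_model = _norm.normalize_bins(self.bins, cfg.normalization())
        m_adj = bins["M_adj"].to_numpy()
        sigma = _mixture.estimate_sigma_mad(m_adj)
        params, diag = _mixture.fit_mixture(m_adj, sigma)
        warning = _mixture.check_common_fraction(params)
        emissions = _mixture.emission_probabilities(m_adj, params)
        seqs = []
        offset = 0
        for _, grp in bins.groupby("cluster_id", sort=True):
            seqs.append(emissions[offset:offset + len(grp)])
            offset += len(grp)
        train = _hmm.train_transitions(seqs, _hmm.HMMModel(), stop or cfg.stop())
        hmm_model = _hmm.HMMModel(train.transitions)
        paths = _hmm.decode_all(seqs, hmm_model)
        bins["state"] = np.concatenate(paths)
        return ClipDifferentialResults(
            model=self,
            normalization=norm_model,
            mixture=params,
            mixture_diagnostics=diag,
            common_fraction_warning=warning,
            transitions=train.transitions,
            hmm_iterations=train.iterations_used,
            hmm_converged=train.converged,
            log_likelihood_trace=train.log_likelihood_trace,
            state_paths=paths,
        )


@dataclass
class ClipDifferentialResults:
    """Fitted estimates, diagnostics and decoded states for one comparison."""

    model: ClipDifferentialModel
    normalization: _norm.NormalizationModel
    mixture: _mixture.MixtureParams
    mixture_diagnostics: _mixture.EstimationDiagnostics
    common_fraction_warning: Optional[str]
    transitions: np.ndarray
    hmm_iterations: int
    hmm_converged: bool
    log_likelihood_trace: list[float]
    state_paths: list[np.ndarray]
    _regions: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def bins(self) -> pd.DataFrame:
        return self.model.bins

    @property
    def regions(self) -> pd.DataFrame:
        """Same-state runs of adjacent bins merged into regions."""
        if self._regions is None:
            self._regions = _reporting.merge_state_runs(self.model.bins)
        return self._regions

    def state_counts(self) -> pd.Series:
        return self.model.bins["state"].value_counts().reindex(range(3), fill_value=0)

    def filter_regions(self, state: int, min_mean_intensity: float,
                       which_condition: int) -> pd.DataFrame:
        return _reporting.filter_regions(self.regions, state,
                                         min_mean_intensity, which_condition)

    def write_outputs(self, out_prefix: str) -> list[str]:
        """Write BED + per-bin TXT + the eight bedGraph tracks."""
        return _reporting.write_outputs(self.regions, self.model.bins,
                                        self.model.total_tracks,
                                        self.model.mutant_tracks, out_prefix)

    def summary(self) -> str:
        """Human-readable estimation summary."""
        d = self.mixture_diagnostics
        counts = self.state_counts()
        lines = [
            "Differential CLIP-seq comparison",
            "=" * 48,
            f"bins: {len(self.model.bins)}   clusters: {len(self.model.clusters) if self.model.clusters is not None else 'n/a'}",
            "",
            "MA normalization  M = a + b*A",
            f"  a (intercept)     {self.normalization.a: .6f}",
            f"  b (slope)         {self.normalization.b: .6f}",
            f"  bins in fit       {self.normalization.n_fit}",
            "",
            "Emission mixture on adjusted M",
            f"  sigma (MAD)       {self.mixture.sigma: .6f}",
            f"  p (outer weight)  {self.mixture.p: .6f}",
            f"  mu (|outer mean|) {self.mixture.mu: .6f}",
            f"  common fraction   {self.mixture.common_fraction: .4f}",
            f"  log-likelihood    {d.log_likelihood: .4f}  (n={d.n})",
            "",
            f"HMM transitions ({self.hmm_iterations} iterations, "
            f"converged={self.hmm_converged})",
        ]
        for r in range(3):
            lines.append("  " + "  ".join(f"{self.transitions[r, s]:.4f}"
                                          for s in range(3)))
        lines.append("")
        lines.append("Decoded bin states")
        for s, name in enumerate(STATE_NAMES):
            lines.append(f"  {s} {name:<16} {int(counts[s])}")
        if self.common_fraction_warning:
            lines += ["", "WARNING: " + self.common_fraction_warning]
        return "\n".join(lines)
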