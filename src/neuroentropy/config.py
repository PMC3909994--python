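"""Generator configuration for the synthetic placebo/drug infusion design.

The defaults encode the study geometry the analyses assume: nine canonical
resting-state networks, a 12-minute eyes-closed scan sampled every 3 s
(240 timepoints), and a 60-s intravenous infusion beginning midway through
the scan (onset at timepoint 120, 20 timepoints long). The infusion window
itself is treated as a transition period and excluded from both the pre and
the post analysis segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .exceptions import ConfigurationError

#: The nine canonical resting-state networks used by the voxel generator,
#: split into sensory/motor networks (coupling never changes) and high-level
#: association networks (coupling becomes variable post-infusion in the
#: drug-like condition).
SENSORY_NETWORKS_9 = (
    "visual-medial",
    "visual-occipital",
    "visual-lateral",
    "sensorimotor",
    "auditory",
)
ASSOCIATION_NETWORKS_9 = (
    "default-mode",
    "executive-control",
    "frontoparietal-left",
    "frontoparietal-right",
)
NETWORK_LABELS_9 = SENSORY_NETWORKS_9 + ASSOCIATION_NETWORKS_9

#: Default ROI names for the 4-node motif analysis: bilateral hippocampus and
#: bilateral anterior cingulate cortex.
ROI_NAMES_4 = ("hippocampus-left", "hippocampus-right", "acc-left", "acc-right")

CONDITIONS = ("placebo_like", "drug_like")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic BOLD-like data generator.

    Parameters
    ----------
    n_networks, voxels_per_network
        Voxel-level dataset geometry; labels follow :data:`NETWORK_LABELS_9`
        when ``n_networks == 9``, otherwise ``network-01 ...``.
    n_rois
        Number of regions in the ROI-level (motif) dataset.
    n_timepoints, sampling_interval
        Scan length in samples and repetition time in seconds.
    infusion_onset, infusion_duration
        Start index and length (timepoints) of the infusion window.
    condition
        ``placebo_like`` (stationary coupling throughout) or ``drug_like``
        (voxel-network coupling becomes temporally variable post-infusion in
        association networks; ROI regime dynamics speed up and widen).
    coupling_sd_post
        Stationary standard deviation of the post-infusion coupling-weight
        fluctuation in the drug-like condition (dimensionless, >= 0).
    n_regimes, switch_rate
        Hidden-regime count and per-step switch probability used by the ROI
        generator *post-infusion in the drug-like condition*.
    n_regimes_baseline, switch_rate_baseline
        Regime dynamics used pre-infusion and throughout the placebo-like
        condition.
    noise_sd
        Voxel-level white measurement-noise standard deviation (> 0).
    roi_noise_sd
        ROI-level measurement-noise standard deviation; small by default so
        windowed correlations track the hidden regime pattern.
    seed
        Root seed; all substreams derive from it deterministically.
    sensory_networks
        Labels whose coupling never changes post-infusion. ``None`` selects
        :data:`SENSORY_NETWORKS_9` for the 9-network default and the empty
        set otherwise.
    """

    n_networks: int = 9
    voxels_per_network: int = 16
    n_rois: int = 4
    n_timepoints: int = 240
    sampling_interval: float = 3.0
    infusion_onset: int = 120
    infusion_duration: int = 20
    condition: str = "placebo_like"
    coupling_sd_post: float = 0.5
    n_regimes: int = 8
    switch_rate: float = 0.2
    n_regimes_baseline: int = 2
    switch_rate_baseline: float = 0.05
    noise_sd: float = 0.5
    roi_noise_sd: float = 0.05
    seed: int = 0
    sensory_networks: tuple = field(default=None)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first violated invariant."""
        for name in ("n_networks", "voxels_per_network", "n_rois", "n_timepoints"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.sampling_interval <= 0:
            raise ConfigurationError(
                f"sampling_interval must be > 0, got {self.sampling_interval}"
            )
        if not 0 <= self.infusion_onset < self.n_timepoints:
            raise ConfigurationError(
                f"infusion_onset must lie in [0, n_timepoints), got {self.infusion_onset}"
            )
        if self.infusion_duration < 0:
            raise ConfigurationError("infusion_duration must be >= 0")
        if self.infusion_onset + self.infusion_duration >= self.n_timepoints:
            raise ConfigurationError(
                "infusion_onset + infusion_duration must be < n_timepoints "
                f"({self.infusion_onset} + {self.infusion_duration} >= {self.n_timepoints})"
            )
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.coupling_sd_post < 0:
            raise ConfigurationError("coupling_sd_post must be >= 0")
        if self.n_regimes < 1 or self.n_regimes_baseline < 1:
            raise ConfigurationError("n_regimes and n_regimes_baseline must be >= 1")
        for name in ("switch_rate", "switch_rate_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.roi_noise_sd < 0:
            raise ConfigurationError("roi_noise_sd must be >= 0")
        if self.sensory_networks is not None:
            unknown = set(self.sensory_networks) - set(self.network_labels())
            if unknown:
                raise ConfigurationError(f"unknown sensory_networks labels: {sorted(unknown)}")

    # -- derived geometry -------------------------------------------------

    def network_labels(self) -> tuple:
        if self.n_networks == 9:
            return NETWORK_LABELS_9
        return tuple(f"network-{i + 1:02d}" for i in range(self.n_networks))

    def sensory_labels(self) -> tuple:
        if self.sensory_networks is not None:
            return tuple(self.sensory_networks)
        return SENSORY_NETWORKS_9 if self.n_networks == 9 else ()

    def association_labels(self) -> tuple:
        sensory = set(self.sensory_labels())
        return tuple(l for l in self.network_labels() if l not in sensory)

    def roi_names(self) -> tuple:
        if self.n_rois == 4:
            return ROI_NAMES_4
        return tuple(f"roi-{i + 1:02d}" for i in range(self.n_rois))

    def pre_segment(self) -> tuple:
        """Half-open [0, infusion_onset)."""
        return (0, self.infusion_onset)

    def post_segment(self) -> tuple:
        """Half-open [infusion_onset + infusion_duration, n_timepoints)."""
        return (self.infusion_onset + self.infusion_duration, self.n_timepoints)

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))
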