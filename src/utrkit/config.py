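"""Default parameters for every pipeline stage.

Every threshold used across the toolkit lives here with its standard value,
so the CLI, the library functions, and the tests agree on a single source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class RunConfig:
    # cleavage-site atlas
    peak_radius: int = 30                 # nt, local-mode merge radius
    rpm_threshold: float = 5.0            # reads per million, strict >
    classify_window: int = 40             # nt window centered on 3' ends
    cluster_tpm_min: float = 3.0          # external atlas cluster support
    priming_window: int = 20              # nt downstream for A-content
    priming_a_fraction: float = 0.65
    priming_a_run: int = 8
    five_ext: int = 1000                  # nt 5'-end extension
    three_ext: int = 5000                 # nt 3'-end extension
    minor_max_celltypes: int = 10         # usage-class rule

    # utrome
    truncation_length: int = 500          # nt kept from the 3' end
    dedup_distance: int = 50              # nt, strict < collapses
    merge_distance: int = 200             # nt, strict < merges counts

    # simulation
    read_length: int = 100
    dist_mean: float = 300.0
    dist_sd: float = 100.0
    sim_replicates: int = 10

    # statistics
    n_boot: int = 10_000
    ci_boot: int = 2000
    min_cells_per_gene: int = 50
    utr_fraction_threshold: float = 0.10  # multi-UTR qualifying isoform
    switching_min_cells: int = 200
    switching_min_tpm: float = 5.0
    fc_threshold: float = 1.5
    dwui_threshold: float = 0.10
    q_threshold: float = 0.05

    # perturbation analysis
    perturb_min_cells: int = 30
    perturb_tpm_min: float = 5.0
    wui_band: tuple = (0.1, 0.9)
    n_pcs: int = 30
    knn_rounds: tuple = (5, 4, 3)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULTS = RunConfig()
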