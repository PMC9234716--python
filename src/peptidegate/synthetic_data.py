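"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Three generators with a shared :class:`PlantedTruth` container:

* clade-labeled alignments with planted specificity-determining columns
  (foreground-conserved, background drawn from other physicochemical
  classes), optional redundant duplicates and out-of-length-window
  sequences for exercising the curation filters;
* C3-symmetric toy trimers whose designated "pocket" residues are placed
  within a chosen radius of the adjacent subunit while all other residues
  are kept well separated;
* Hill-model dose-response tables and biexponential current traces with
  multiplicative noise (oocyte responses scale with expression level, so
  noise on peaks is proportional, not additive).

Everything is seeded; equal seeds and configs yield byte-identical outputs.
The generators deliberately share the scan's six-class physicochemical
scheme so that "conserved in terms of physicochemical properties" means the
same thing when planting and when detecting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import biotite.structure as struc

from .physchem import AMINO_ACIDS, CLASSES, class_members, residue_class
from .sequence_curation import SequenceRecord
from .clade_contrast import BACKGROUND, EXCLUDED, FOREGROUND, CladeLabeledAlignment
from .structure_mapping import TrimerStructure
from .ephys_stats import ApplicationWindow, CurrentTrace, DoseResponseSet

__all__ = [
    "MsaSimConfig",
    "TraceSimConfig",
    "PlantedTruth",
    "simulate_msa",
    "simulate_trimer",
    "simulate_dose_response",
    "simulate_trace",
    "simulate_potency_pairs",
    "simulate_enhancement_pairs",
    "DEFAULT_CONCENTRATION_LADDER",
]

#: half-log agonist ladder from 30 nM to 100 µM (M), the standard
#: concentration-response protocol emulated here
DEFAULT_CONCENTRATION_LADDER: tuple[float, ...] = (
    3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4,
)


@dataclass
class PlantedTruth:
    """Generator ground truth carried alongside synthetic data as the test oracle."""

    sdp_columns: tuple[int, ...] = ()
    pocket_residues: tuple[tuple[str, int], ...] = ()
    true_ec50: float | None = None  # M
    true_hill: float | None = None
    true_imax: float | None = None  # µA
    true_ratio: float | None = None
    true_fold_enhancement: float | None = None
    true_peak: float | None = None  # µA, analytic trace peak
    duplicate_ids: dict[str, str] = field(default_factory=dict)
    outlier_ids: tuple[str, ...] = ()
    outlier_records: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.true_ec50 is not None and self.true_ec50 <= 0:
            raise ValueError("true_ec50 must be positive")
        if self.true_hill is not None and self.true_hill <= 0:
            raise ValueError("true_hill must be positive")
        if self.true_fold_enhancement is not None and self.true_fold_enhancement < 0:
            raise ValueError("true_fold_enhancement must be nonnegative")


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class MsaSimConfig:
    """Parameters of the planted-column alignment generator.

    ``within_class_noise`` is the probability that a foreground residue at a
    planted column is replaced by a different residue of the same
    physicochemical class — planting class-level rather than identity-level
    conservation, which is how the screen's "either" mode gets stressed.
    ``background_profile`` is a frequency vector over the 20-letter alphabet
    (alphabetical order) applied to every non-planted column; uniform when
    omitted.
    """

    n_foreground: int = 20
    n_background: int = 50
    n_columns: int = 200
    planted_columns: tuple[int, ...] = ()
    within_class_noise: float = 0.0
    background_profile: tuple[float, ...] | None = None
    n_redundant_duplicates: int = 0
    n_length_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foreground < 2 or self.n_background < 2:
            raise ValueError("need at least 2 foreground and 2 background sequences")
        if any(not 1 <= c <= self.n_columns for c in self.planted_columns):
            raise ValueError("planted_columns must lie in [1, n_columns]")
        if len(set(self.planted_columns)) != len(self.planted_columns):
            raise ValueError("planted_columns must be unique")
        if not 0 <= self.within_class_noise <= 1:
            raise ValueError("within_class_noise must be in [0,1]")
        if self.background_profile is not None:
            p = np.asarray(self.background_profile, dtype=float)
            if p.shape != (20,):
                raise ValueError("background_profile must have 20 entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("background_profile must be nonnegative and sum to 1")


def simulate_msa(config: MsaSimConfig) -> tuple[CladeLabeledAlignment, PlantedTruth]:
    """Generate a clade-labeled alignment with planted SDP columns.

    At planted columns all foreground rows share one residue (up to
    within-class noise) while every background residue is drawn from a
    *different* physicochemical class; all other columns are iid draws from
    the background profile for foreground and background alike, so they
    carry no clade signal. Requested exact duplicates are appended with the
    source row's label, and out-of-length-window unaligned sequences (the
    curation fodder) are attached to the truth record, labeled ``excluded``.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    profile = (
        np.full(20, 1 / 20)
        if config.background_profile is None
        else np.asarray(config.background_profile, dtype=float)
    )
    n_fg, n_bg, n_col = config.n_foreground, config.n_background, config.n_columns
    planted = set(config.planted_columns)

    fg = np.empty((n_fg, n_col), dtype="<U1")
    bg = np.empty((n_bg, n_col), dtype="<U1")
    for col in range(1, n_col + 1):
        if col in planted:
            consensus = str(rng.choice(alphabet))
            cls = residue_class(consensus)
            siblings = [a for a in class_members(cls) if a != consensus]
            if config.within_class_noise > 0 and not siblings:
                raise ValueError(
                    f"cannot add within-class noise at column {col}: class "
                    f"{cls!r} has a single member"
                )
            col_fg = np.full(n_fg, consensus, dtype="<U1")
            if config.within_class_noise > 0:
                flip = rng.random(n_fg) < config.within_class_noise
                col_fg[flip] = rng.choice(siblings, size=int(flip.sum()))
            other = [a for a in AMINO_ACIDS if residue_class(a) != cls]
            if not other:
                raise ValueError(
                    f"column {col}: no residue outside class {cls!r} available"
                )
            col_bg = rng.choice(other, size=n_bg)
            fg[:, col - 1] = col_fg
            bg[:, col - 1] = col_bg
        else:
            draws = rng.choice(alphabet, size=n_fg + n_bg, p=profile)
            fg[:, col - 1] = draws[:n_fg]
            bg[:, col - 1] = draws[n_fg:]

    records: list[SequenceRecord] = []
    partition: dict[str, str] = {}
    for i in range(n_fg):
        rid = f"fg_{i + 1:03d}"
        records.append(SequenceRecord(rid, "".join(fg[i])))
        partition[rid] = FOREGROUND
    for i in range(n_bg):
        rid = f"bg_{i + 1:03d}"
        records.append(SequenceRecord(rid, "".join(bg[i])))
        partition[rid] = BACKGROUND

    duplicate_ids: dict[str, str] = {}
    for k in range(config.n_redundant_duplicates):
        src = records[int(rng.integers(len(records)))]
        rid = f"dup_{k + 1:03d}_{src.id}"
        records.append(SequenceRecord(rid, src.residues))
        partition[rid] = partition[src.id]
        duplicate_ids[rid] = src.id

    outliers: list[SequenceRecord] = []
    for k in range(config.n_length_outliers):
        length = 150 if k % 2 == 0 else 1200
        seq = "".join(rng.choice(alphabet, size=length))
        rid = f"outlier_{k + 1:03d}"
        outliers.append(SequenceRecord(rid, seq))

    truth = PlantedTruth(
        sdp_columns=tuple(sorted(planted)),
        duplicate_ids=duplicate_ids,
        outlier_ids=tuple(o.id for o in outliers),
        outlier_records=outliers,  # unaligned; kept off the alignment
    )
    aln = CladeLabeledAlignment(records, partition)
    return aln, truth


# ---------------------------------------------------------------------------
# Trimers


def simulate_trimer(
    n_residues_per_chain: int,
    pocket_residues: list[int] | tuple[int, ...] = (),
    interface_radius: float = 5.0,
    seed: int = 0,
) -> tuple[TrimerStructure, PlantedTruth]:
    """C3-symmetric Cα-only toy trimer with planted interface residues.

    Chain A is built and chains B and C are its 120° and 240° rotations
    about the z axis. Non-pocket residues stack at a ring radius of twice
    the interface radius, so the closest approach between chains is well
    beyond 1.5x the interface radius; pocket residues sit near the symmetry
    axis in a separate z band, where each lies within ``interface_radius``
    of its own rotational image on the adjacent chain. Output is writable
    as a valid PDB.
    """
    pocket = sorted(set(int(r) for r in pocket_residues))
    n = int(n_residues_per_chain)
    if any(not 1 <= r <= n for r in pocket):
        raise ValueError("pocket_residues must lie in [1, n_residues_per_chain]")
    if n < max(len(pocket), 2):
        raise ValueError(
            f"{n} residues per chain cannot satisfy the separation constraints"
        )
    r = float(interface_radius)
    if r <= 0:
        raise ValueError("interface_radius must be positive")
    rng = np.random.default_rng(seed)

    ring_radius = 2.0 * r  # inter-chain ring distance = 2r*sqrt(3) > 1.5r
    pocket_radius = r / np.sqrt(3.0) * 0.95  # image distance = r*sqrt(3)/sqrt(3)*0.95 < r
    dz = 2.0
    pocket_dz = 1.5
    pocket_z0 = -(2.0 * r + 4.0)  # keeps the pocket band > 1.5r from the ring stack

    chain_a = np.empty((n, 3))
    stack_i = 0
    for res in range(1, n + 1):
        if res in pocket:
            k = pocket.index(res)
            jitter = rng.normal(0.0, 0.02, size=2)
            chain_a[res - 1] = (
                pocket_radius + jitter[0],
                jitter[1],
                pocket_z0 - k * pocket_dz,
            )
        else:
            jitter = rng.normal(0.0, 0.05, size=3)
            chain_a[res - 1] = (
                ring_radius + jitter[0],
                jitter[1],
                stack_i * dz + jitter[2],
            )
            stack_i += 1

    def rot(theta: float) -> np.ndarray:
        c, s = np.cos(theta), np.sin(theta)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    coords = np.concatenate(
        [chain_a @ rot(k * 2.0 * np.pi / 3.0).T for k in range(3)]
    )
    n_atoms = 3 * n
    arr = struc.AtomArray(n_atoms)
    arr.coord = coords
    arr.chain_id = np.repeat(["A", "B", "C"], n)
    arr.res_id = np.tile(np.arange(1, n + 1), 3)
    arr.res_name = np.full(n_atoms, "GLY")
    arr.atom_name = np.full(n_atoms, "CA")
    arr.element = np.full(n_atoms, "C")
    arr.hetero = np.full(n_atoms, False)

    structure = TrimerStructure(arr)
    truth = PlantedTruth(
        pocket_residues=tuple(
            (chain, res) for chain in "ABC" for res in pocket
        )
    )
    _check_separation(structure, pocket, r)
    return structure, truth


def _check_separation(structure: TrimerStructure, pocket: list[int], r: float) -> None:
    """Verify the generator's own geometric guarantees; raise if violated."""
    from .structure_mapping import min_interchain_distance

    pocket_set = set(pocket)
    n = int(structure.atoms.res_id.max())
    for res in range(1, n + 1):
        d, _ = min_interchain_distance(structure, "A", res, atom_mode="CA")
        if res in pocket_set and d > r:
            raise RuntimeError(f"planted pocket residue {res} at {d:.2f} Å > {r}")
        if res not in pocket_set and d <= 1.5 * r:
            raise RuntimeError(f"non-pocket residue {res} at {d:.2f} Å <= 1.5x{r}")


# ---------------------------------------------------------------------------
# Dose-response tables


def simulate_dose_response(
    true_ec50: float,
    true_hill: float = 1.0,
    true_imax: float = 1.0,
    concentrations: tuple[float, ...] | None = None,
    n_recordings: int = 5,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
    construct: str = "WT",
    ligand: str = "agonist",
    recordings_per_batch: int = 5,
) -> tuple[DoseResponseSet, PlantedTruth]:
    """Hill-model peak tables with multiplicative Gaussian noise.

    peak = Imax * c^n / (c^n + EC50^n) * (1 + eps), eps ~ N(0, fraction^2),
    independently per point per recording. Recording and batch identifiers
    are assigned (consecutive recordings share a batch, emulating recording
    days).
    """
    if true_ec50 <= 0 or true_hill <= 0:
        raise ValueError("true_ec50 and true_hill must be positive")
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be nonnegative")
    concs = np.asarray(
        DEFAULT_CONCENTRATION_LADDER if concentrations is None else concentrations,
        dtype=float,
    )
    if (concs <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in range(n_recordings):
        eps = rng.normal(0.0, noise_sd_fraction, size=len(concs))
        clean = true_imax * concs**true_hill / (concs**true_hill + true_ec50**true_hill)
        peaks = clean * (1.0 + eps)
        for c, p in zip(concs, peaks):
            rows.append(
                {
                    "recording_id": f"rec_{rec + 1:03d}",
                    "batch_id": f"batch_{rec // recordings_per_batch + 1:02d}",
                    "concentration_M": c,
                    "peak_uA": p,
                    "construct": construct,
                    "ligand": ligand,
                }
            )
    ds = DoseResponseSet(pd.DataFrame(rows), construct=construct, ligand=ligand)
    truth = PlantedTruth(true_ec50=true_ec50, true_hill=true_hill, true_imax=true_imax)
    return ds, truth


# ---------------------------------------------------------------------------
# Current traces


@dataclass(frozen=True)
class TraceSimConfig:
    """Biexponential current-pulse generator settings.

    The rise follows 1 - exp(-t/tau_activation); an optional
    exp(-t/tau_desensitization) decay is superimposed and the envelope is
    rescaled so its analytic extremum equals ``peak_amplitude`` (negative
    for inward currents). Noise is white Gaussian on the samples.
    """

    duration: float = 10.0  # s
    sampling_rate: float = 500.0  # Hz
    application_window: tuple[float, float] = (2.0, 7.0)
    tau_activation: float = 0.1  # s
    tau_desensitization: float | None = None  # s
    peak_amplitude: float = -5.0  # µA, negative = inward
    noise_sd: float = 0.0  # µA
    seed: int = 0
    ligand: str = ""
    concentration: float = float("nan")  # M

    def __post_init__(self) -> None:
        start, end = self.application_window
        if not (0 <= start < end <= self.duration):
            raise ValueError("application window must lie within the trace duration")
        if self.tau_activation <= 0:
            raise ValueError("tau_activation must be positive")
        if self.tau_desensitization is not None and self.tau_desensitization <= 0:
            raise ValueError("tau_desensitization must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _envelope(t: np.ndarray, cfg: TraceSimConfig) -> tuple[np.ndarray, float]:
    """Unit envelope inside the window and the time of its analytic peak."""
    rise = 1.0 - np.exp(-t / cfg.tau_activation)
    if cfg.tau_desensitization is None:
        return rise, float("inf")
    decay = np.exp(-t / cfg.tau_desensitization)
    t_star = cfg.tau_activation * np.log(1.0 + cfg.tau_desensitization / cfg.tau_activation)
    peak_val = (1.0 - np.exp(-t_star / cfg.tau_activation)) * np.exp(
        -t_star / cfg.tau_desensitization
    )
    return rise * decay / peak_val, t_star


def simulate_trace(config: TraceSimConfig) -> tuple[CurrentTrace, PlantedTruth]:
    """One current pulse: zero baseline outside the application window.

    With desensitization the analytic peak time is
    t* = tau_act * ln(1 + tau_des/tau_act); the envelope is normalized so
    the current at t* equals ``peak_amplitude``. The true peak is stored in
    the returned :class:`PlantedTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate)) + 1
    time = np.arange(n) / config.sampling_rate
    current = np.zeros(n)
    start, end = config.application_window
    inside = (time >= start) & (time <= end)
    t_rel = time[inside] - start
    env, _ = _envelope(t_rel, config)
    current[inside] = config.peak_amplitude * env
    if config.noise_sd > 0:
        current = current + rng.normal(0.0, config.noise_sd, size=n)
    window = ApplicationWindow(start, end, config.ligand, config.concentration)
    trace = CurrentTrace(time, current, [window])
    if config.tau_desensitization is None:
        true_peak = config.peak_amplitude * (
            1.0 - np.exp(-(end - start) / config.tau_activation)
        )
    else:
        true_peak = config.peak_amplitude
    return trace, PlantedTruth(true_peak=float(true_peak))


def _two_pulse_trace(
    amp_a: float,
    amp_b: float,
    ligand_a: str,
    ligand_b: str,
    conc_a: float,
    conc_b: float,
    noise_sd: float,
    rng: np.random.Generator,
    sampling_rate: float = 500.0,
    tau_activation: float = 0.1,
) -> CurrentTrace:
    """One recording with two applications separated by a washout."""
    pulse, wash = 4.0, 4.0
    duration = 2.0 + pulse + wash + pulse + 2.0
    n = int(round(duration * sampling_rate)) + 1
    time = np.arange(n) / sampling_rate
    current = np.zeros(n)
    windows = []
    for amp, lig, conc, start in (
        (amp_a, ligand_a, conc_a, 2.0),
        (amp_b, ligand_b, conc_b, 2.0 + pulse + wash),
    ):
        end = start + pulse
        inside = (time >= start) & (time <= end)
        current[inside] = amp * (1.0 - np.exp(-(time[inside] - start) / tau_activation))
        windows.append(ApplicationWindow(start, end, lig, conc))
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n)
    return CurrentTrace(time, current, windows)


def simulate_potency_pairs(
    true_ratio: float,
    n_recordings: int = 14,
    noise_sd_fraction: float = 0.05,
    conc_a: float = 3e-6,
    conc_b: float = 30e-6,
    base_amplitude: float = -5.0,
    seed: int = 0,
    ligand: str = "FMRFa",
) -> tuple[list[CurrentTrace], PlantedTruth]:
    """Paired sub-maximal/maximal recordings with a planted potency ratio.

    Each recording applies ``conc_a`` then ``conc_b`` to the same oocyte;
    the saturating amplitude varies between oocytes (lognormal expression
    scatter) and both peaks carry independent multiplicative noise, so the
    per-recording ratio is true_ratio x (1+eps_a)/(1+eps_b).
    """
    if true_ratio < 0:
        raise ValueError("true_ratio must be nonnegative")
    rng = np.random.default_rng(seed)
    traces = []
    for _ in range(n_recordings):
        scale = rng.lognormal(0.0, 0.3)
        amp_b = base_amplitude * scale * (1.0 + rng.normal(0.0, noise_sd_fraction))
        amp_a = base_amplitude * scale * true_ratio * (
            1.0 + rng.normal(0.0, noise_sd_fraction)
        )
        traces.append(
            _two_pulse_trace(
                amp_a, amp_b, ligand, ligand, conc_a, conc_b,
                noise_sd=abs(base_amplitude) * 0.002, rng=rng,
            )
        )
    return traces, PlantedTruth(true_ratio=true_ratio)


def simulate_enhancement_pairs(
    true_fold: float,
    n_recordings: int = 7,
    noise_sd_fraction: float = 0.10,
    control_amplitude: float = -0.5,
    conditioning_ph: float = 7.0,
    test_ph: float = 5.3,
    seed: int = 0,
    peptide: str = "FRRFa",
) -> tuple[list[CurrentTrace], PlantedTruth]:
    """Paired conditioning-protocol recordings with a planted fold-enhancement.

    Pulse a: proton test pulse after conditioning in desensitizing pH alone;
    pulse b: the same test pulse after conditioning with peptide added. The
    planted fold is |peak_b|/|peak_a|; both peaks carry multiplicative
    noise.
    """
    if true_fold < 0:
        raise ValueError("true_fold must be nonnegative")
    rng = np.random.default_rng(seed)
    test_conc = 10.0 ** (-test_ph)
    traces = []
    for _ in range(n_recordings):
        scale = rng.lognormal(0.0, 0.2)
        amp_a = control_amplitude * scale * (1.0 + rng.normal(0.0, noise_sd_fraction))
        amp_b = control_amplitude * scale * true_fold * (
            1.0 + rng.normal(0.0, noise_sd_fraction)
        )
        tr = _two_pulse_trace(
            amp_a, amp_b,
            f"pH {test_ph} after pH {conditioning_ph}",
            f"pH {test_ph} after pH {conditioning_ph} + {peptide}",
            test_conc, test_conc,
            noise_sd=abs(control_amplitude) * 0.002, rng=rng,
        )
        traces.append(tr)
    return traces, PlantedTruth(true_fold_enhancement=true_fold)
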