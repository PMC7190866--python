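"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the three arms of the screen:

* a single-dose, multi-line viability screen with planted per-line potencies
  (Hill-model truth, multiplicative log-normal well noise),
* drug-pair dose matrices with a planted Bliss-deviation interaction term,
* small peak/TSS/differential-expression fixtures with planted direct
  targets, where every decoy gene violates exactly one calling condition.

All randomness descends from ``SimConfig.seed`` through named child streams,
so a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bliss import DoseMatrix
from .plate_io import DEFAULT_CONTROL_LABEL, ScreenDataset, WellAddress, plate_dims

__all__ = [
    "LinePotency",
    "CompoundTruth",
    "InteractionTruth",
    "SimConfig",
    "GenomicTruth",
    "generate_single_dose_screen",
    "generate_dose_matrix",
    "generate_genomic_fixture",
    "example_screen_truths",
    "DEFAULT_PANEL",
]

#: the three-line isogenic panel emulated by default: a gain-of-function
#: missense p53 mutant, the wild-type revertant, and the parental null line
DEFAULT_PANEL = ("p53_R158G", "p53_WT", "p53_NULL")


def stream(seed: int, label: str) -> np.random.Generator:
    """Named child RNG: stream(seed, label) is stable across runs/platforms."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class LinePotency:
    """Hill-model truth for one compound in one cell line.

    ``ed50`` is the midpoint concentration in uM, ``hill`` the unitless slope
    (> 0) and ``emax`` the maximal fractional inhibition in [0, 1].
    """

    ed50: float
    hill: float = 1.0
    emax: float = 1.0

    def __post_init__(self) -> None:
        if not self.ed50 > 0:
            raise ValueError(f"ed50 must be > 0, got {self.ed50}")
        if self.hill < 0:
            raise ValueError(f"hill must be >= 0, got {self.hill}")
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError(f"emax must be in [0, 1], got {self.emax}")

    def inhibition(self, dose: float | np.ndarray) -> float | np.ndarray:
        """True fractional inhibition emax * d^h / (ed50^h + d^h)."""
        d = np.asarray(dose, dtype=float)
        out = np.zeros_like(d)
        pos = d > 0
        out[pos] = self.emax * d[pos] ** self.hill / (self.ed50**self.hill + d[pos] ** self.hill)
        return float(out) if np.isscalar(dose) or out.ndim == 0 else out


@dataclass(frozen=True)
class CompoundTruth:
    compound_id: str
    potency: Mapping[str, LinePotency]

    def inhibition(self, cell_line: str, dose: float | np.ndarray):
        if cell_line not in self.potency:
            raise KeyError(f"cell line {cell_line!r} missing from truth for {self.compound_id}")
        return self.potency[cell_line].inhibition(dose)


@dataclass(frozen=True)
class InteractionTruth:
    """Planted Bliss-deviation term per cell line, in inhibition space.

    Positive delta means more inhibition than the Bliss expectation
    (synergy); negative means antagonism; 0 means independence. Applied to
    combination wells only, never to single-agent margins; the resulting
    true inhibition is clipped to [0, 1].
    """

    deltas: Mapping[str, float]

    def for_line(self, cell_line: str) -> float:
        return float(self.deltas.get(cell_line, 0.0))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    plate_format: int = 384
    n_replicates: int = 3
    noise_cv: float = 0.05
    control_wells_per_plate: int = 16
    baseline_luminescence: float = 10_000.0
    control_label: str = DEFAULT_CONTROL_LABEL
    #: sd of an optional per-plate log-scale shift; defaults off
    plate_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.control_wells_per_plate < 1:
            raise ValueError("need at least one control well per plate")
        plate_dims(self.plate_format)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _noise_sigma(cv: float) -> float:
    # log-normal with log-mean 0 whose coefficient of variation equals cv
    return float(np.sqrt(np.log1p(cv**2)))


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    return rng.lognormal(mean=0.0, sigma=_noise_sigma(cv), size=n)


# ---------------------------------------------------------------------------
# single-dose screen
# ---------------------------------------------------------------------------

def _panel_from_truths(truths: Sequence[CompoundTruth]) -> list[str]:
    if not truths:
        raise ValueError("empty truth list")
    panel = list(truths[0].potency)
    for t in truths:
        if set(t.potency) != set(panel):
            raise ValueError(
                f"compound {t.compound_id} covers lines {sorted(t.potency)}, "
                f"expected {sorted(panel)}"
            )
    return panel


def generate_single_dose_screen(
    config: SimConfig,
    truths: Sequence[CompoundTruth],
    doses: Sequence[float],
) -> ScreenDataset:
    """Simulate the single-dose screen over the full panel.

    Each (cell line, replicate) pair occupies its own plate series; treated
    wells fill the non-control columns row-major, one well per
    (compound, dose); DMSO control wells occupy fixed right-most designated
    columns. Well luminescence is
    ``baseline * (1 - true_inhibition(dose)) * noise`` (times an optional
    plate shift); controls see the baseline times noise only.
    """
    panel = _panel_from_truths(truths)
    doses = [float(d) for d in doses]
    if not doses:
        raise ValueError("need at least one dose")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be strictly positive")

    n_rows, n_cols = plate_dims(config.plate_format)
    n_ctrl_cols = -(-config.control_wells_per_plate // n_rows)  # ceil div
    treated_cols = n_cols - n_ctrl_cols
    if treated_cols < 1:
        raise ValueError("control wells leave no room for treated wells")
    per_plate = n_rows * treated_cols

    jobs = [(t, d) for t in truths for d in doses]
    rows: list[dict] = []
    for line in panel:
        for rep in range(1, config.n_replicates + 1):
            rng = stream(config.seed, f"screen/{line}/rep{rep}")
            for p0 in range(0, len(jobs), per_plate):
                chunk = jobs[p0 : p0 + per_plate]
                plate_id = f"{line}-r{rep}-p{p0 // per_plate + 1}"
                shift = 1.0
                if config.plate_shift_sd > 0:
                    shift = float(np.exp(rng.normal(0.0, config.plate_shift_sd)))
                noise = _noise_factors(rng, config.noise_cv, len(chunk))
                for k, (truth, dose) in enumerate(chunk):
                    addr = WellAddress(k // treated_cols, k % treated_cols)
                    inh = truth.inhibition(line, dose)
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": addr.label,
                            "cell_line": line,
                            "compound": truth.compound_id,
                            "dose_um": dose,
                            "replicate": rep,
                            "luminescence": config.baseline_luminescence
                            * (1.0 - inh)
                            * noise[k]
                            * shift,
                        }
                    )
                ctrl_noise = _noise_factors(rng, config.noise_cv, config.control_wells_per_plate)
                for k in range(config.control_wells_per_plate):
                    addr = WellAddress(k % n_rows, treated_cols + k // n_rows)
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": addr.label,
                            "cell_line": line,
                            "compound": config.control_label,
                            "dose_um": 0.0,
                            "replicate": rep,
                            "luminescence": config.baseline_luminescence * ctrl_noise[k] * shift,
                        }
                    )
    return ScreenDataset(
        records=pd.DataFrame(rows),
        panel=panel,
        provenance={
            "generator": "generate_single_dose_screen",
            "seed": config.seed,
            "noise_cv": config.noise_cv,
            "n_replicates": config.n_replicates,
            "doses_um": doses,
        },
        plate_format=config.plate_format,
        control_label=config.control_label,
    )


# ---------------------------------------------------------------------------
# dose matrices
# ---------------------------------------------------------------------------

def generate_dose_matrix(
    config: SimConfig,
    truth_a: CompoundTruth,
    truth_b: CompoundTruth,
    interaction: InteractionTruth,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    cell_line: str,
) -> DoseMatrix:
    """Simulate a replicated drug-pair dose matrix for one cell line.

    Single-agent margins (dose 0 for the partner) are always included. The
    true combination inhibition is ``clip(fA + fB - fA*fB + delta, 0, 1)``
    with the planted delta applied only where both doses are positive;
    replicate viabilities get multiplicative log-normal noise and the
    returned matrix holds the replicate-averaged fractional inhibition.
    """
    da = np.asarray([float(d) for d in doses_a])
    db = np.asarray([float(d) for d in doses_b])
    if da.size == 0 or db.size == 0:
        raise ValueError("dose grids must be non-empty")
    if (da <= 0).any() or (db <= 0).any():
        raise ValueError("dose grids must be strictly positive (0 margins are added)")
    da = np.concatenate([[0.0], np.sort(da)])
    db = np.concatenate([[0.0], np.sort(db)])

    fa = np.asarray(truth_a.inhibition(cell_line, da))
    fb = np.asarray(truth_b.inhibition(cell_line, db))
    delta = interaction.for_line(cell_line)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    combo = (da[:, None] > 0) & (db[None, :] > 0)
    true_inh = np.clip(expected + delta * combo, 0.0, 1.0)

    rng = stream(config.seed, f"matrix/{truth_a.compound_id}+{truth_b.compound_id}/{cell_line}")
    reps = np.empty((config.n_replicates, da.size, db.size))
    for r in range(config.n_replicates):
        noise = _noise_factors(rng, config.noise_cv, true_inh.size).reshape(true_inh.shape)
        viability = 100.0 * (1.0 - true_inh) * noise
        reps[r] = np.clip(1.0 - viability / 100.0, 0.0, 1.0)
    return DoseMatrix(
        doses_a=da,
        doses_b=db,
        inhibition=reps.mean(axis=0),
        n_replicates=config.n_replicates,
        meta={
            "cell_line": cell_line,
            "drug_a": truth_a.compound_id,
            "drug_b": truth_b.compound_id,
            "planted_delta": delta,
            "seed": config.seed,
        },
    )


# ---------------------------------------------------------------------------
# genomic fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicTruth:
    """Ground truth for a genomic fixture: the planted direct-target genes."""

    planted: tuple[str, ...]
    decoy_kind: Mapping[str, str] = field(default_factory=dict)


_GENE_SPACING = 100_000  # bp between consecutive TSS; isolates each gene's peak


def generate_genomic_fixture(
    config: SimConfig,
    n_genes: int = 50,
    n_planted_targets: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GenomicTruth]:
    """Generate (peak table, TSS table, DEG table, truth) with planted targets.

    Planted genes receive a shortlist-passing peak (fold >= 5, pileup >= 25,
    q < 0.01) within 10 kb of their TSS and |log2FC| > 1.5. Every decoy gene
    violates exactly one condition, cycling through three kinds: a far peak
    (> 10 kb), a weak peak (fails the shortlist), or a small fold change
    (|log2FC| <= 1.2). Coordinates are 0-based half-open; TSS are spaced
    100 kb apart so no peak can qualify a neighbouring gene.
    """
    if n_genes < 0 or n_planted_targets < 0:
        raise ValueError("counts must be non-negative")
    if n_planted_targets > n_genes:
        raise ValueError("n_planted_targets cannot exceed n_genes")

    rng = stream(config.seed, "genomic")
    genes = [f"GENE{i:03d}" for i in range(n_genes)]
    planted = sorted(rng.choice(genes, size=n_planted_targets, replace=False).tolist())
    planted_set = set(planted)

    tss_rows, peak_rows, deg_rows = [], [], []
    decoy_kind: dict[str, str] = {}
    kinds = ("far_peak", "weak_peak", "small_lfc")
    k = 0
    for i, gene in enumerate(genes):
        chrom = "chrS1" if i % 2 == 0 else "chrS2"
        tss = 50_000 + (i // 2) * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append({"gene_id": gene, "chrom": chrom, "tss": tss, "strand": strand})

        sign = -1.0 if rng.random() < 0.3 else 1.0
        if gene in planted_set:
            offset = int(rng.integers(-8_000, 8_001))
            lfc = sign * rng.uniform(2.0, 4.0)
            fold, pileup, q = rng.uniform(6.0, 15.0), int(rng.integers(30, 120)), 10.0 ** -rng.uniform(3, 8)
        else:
            kind = kinds[k % 3]
            k += 1
            decoy_kind[gene] = kind
            if kind == "far_peak":
                offset = int(rng.integers(20_000, 40_000)) * (1 if rng.random() < 0.5 else -1)
                lfc = sign * rng.uniform(2.0, 4.0)
                fold, pileup, q = rng.uniform(6.0, 15.0), int(rng.integers(30, 120)), 10.0 ** -rng.uniform(3, 8)
            elif kind == "weak_peak":
                offset = int(rng.integers(-8_000, 8_001))
                lfc = sign * rng.uniform(2.0, 4.0)
                fail = rng.integers(3)
                fold = rng.uniform(1.0, 4.5) if fail == 0 else rng.uniform(6.0, 15.0)
                pileup = int(rng.integers(3, 20)) if fail == 1 else int(rng.integers(30, 120))
                q = rng.uniform(0.02, 0.5) if fail == 2 else 10.0 ** -rng.uniform(3, 8)
            else:  # small_lfc
                offset = int(rng.integers(-8_000, 8_001))
                lfc = sign * rng.uniform(0.0, 1.2)
                fold, pileup, q = rng.uniform(6.0, 15.0), int(rng.integers(30, 120)), 10.0 ** -rng.uniform(3, 8)
        width = int(rng.integers(200, 800))
        start = max(0, tss + offset - width // 2)
        peak_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + width,
                "fold_enrichment": round(float(fold), 3),
                "pileup": int(pileup),
                "q_value": float(q),
            }
        )
        deg_rows.append({"gene_id": gene, "log2_fold_change": round(float(lfc), 4)})

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "fold_enrichment", "pileup", "q_value"])
    peaks = peaks.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss", "strand"])
    deg = pd.DataFrame(deg_rows, columns=["gene_id", "log2_fold_change"])
    return peaks, tss, deg, GenomicTruth(planted=tuple(planted), decoy_kind=decoy_kind)


# ---------------------------------------------------------------------------
# default study conditions: the 3-line, 200-compound demo screen
# ---------------------------------------------------------------------------

def example_screen_truths(
    seed: int,
    n_compounds: int = 200,
    panel: Sequence[str] = DEFAULT_PANEL,
    n_selective: Mapping[str, int] | None = None,
    n_pan_active: int = 10,
    n_two_line: int = 6,
) -> tuple[list[CompoundTruth], dict[str, str]]:
    """Planted compound panel emulating the three-line screen.

    Defaults plant 17 mutant-line-selective compounds (the screen's headline
    class) plus 8 selective for each of the other two lines, 10 pan-active
    and 6 two-line-active compounds; the remainder is inactive. Selective
    compounds have ed50 ~0.03-0.07 uM in their target line and ~50 uM
    elsewhere, so at the screened 0.1/1 uM doses they comfortably clear the
    50% inhibition threshold only in the target line. Returns the truth list
    and a compound_id -> planted class map (e.g. "p53_R158G_selective").
    """
    panel = list(panel)
    if n_selective is None:
        n_selective = {panel[0]: 17, **{ln: 8 for ln in panel[1:]}}
    n_active = sum(n_selective.values()) + n_pan_active + n_two_line
    if n_compounds < n_active:
        raise ValueError(f"n_compounds={n_compounds} smaller than the {n_active} planted active compounds")
    rng = stream(seed, "truth-panel")

    def potent() -> LinePotency:
        return LinePotency(
            ed50=float(rng.uniform(0.03, 0.07)),
            hill=float(rng.uniform(1.0, 2.0)),
            emax=float(rng.uniform(0.92, 1.0)),
        )

    def weak() -> LinePotency:
        return LinePotency(ed50=float(rng.uniform(30.0, 80.0)), hill=1.0, emax=1.0)

    def inert() -> LinePotency:
        return LinePotency(ed50=float(rng.uniform(300.0, 1000.0)), hill=1.0, emax=1.0)

    truths: list[CompoundTruth] = []
    labels: dict[str, str] = {}

    def add(cid: str, label: str, pot: Mapping[str, LinePotency]) -> None:
        truths.append(CompoundTruth(cid, dict(pot)))
        labels[cid] = label

    i = 0
    for line, count in n_selective.items():
        for _ in range(count):
            cid = f"CPD{i:03d}"
            add(cid, f"{line}_selective", {ln: potent() if ln == line else weak() for ln in panel})
            i += 1
    for _ in range(n_pan_active):
        cid = f"CPD{i:03d}"
        add(cid, "pan_active", {ln: potent() for ln in panel})
        i += 1
    for _ in range(n_two_line):
        cid = f"CPD{i:03d}"
        pair = list(rng.choice(panel, size=2, replace=False))
        add(cid, "other_selective_pattern", {ln: potent() if ln in pair else weak() for ln in panel})
        i += 1
    while i < n_compounds:
        cid = f"CPD{i:03d}"
        add(cid, "inactive", {ln: inert() for ln in panel})
        i += 1
    return truths, labels
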