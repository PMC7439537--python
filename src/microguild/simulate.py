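"""Synthetic two-arm fiber-intervention datasets with planted guild structure.

Baseline log-abundances follow a log-normal spectrum and are closed to a
fixed sequencing depth by multinomial sampling. Treatment-arm subjects
receive CLR-scale shifts that are correlated within planted guilds, scaled
by a log-normal per-subject susceptibility; control-arm subjects receive
noise only. Propionate responses are linearly linked to guild shifts, and a
per-subject temporal archetype fixes the sign of the W1 -> W6 propionate
increment. Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from microguild.data_model import (
    AbundanceTable,
    MetadataTable,
    SampleMetadata,
    ScfaProfile,
    StoolDiary,
    StudyDesign,
    write_abundance_table,
    write_metadata_table,
    write_scfa_table,
    write_stool_diary_table,
)
from microguild.guilds import GUILD_PREFIX, ShiftMatrix
from microguild.scfa import NONRESPONDER, RESPONDER

BACKGROUND = "none"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic intervention study."""

    n_subjects: int = 31
    n_treatment: int = 15
    female_fraction: float = 21 / 31
    n_otus: int = 100
    guild_sizes: tuple[int, ...] = (10, 10, 10, 10)
    rho_within: float = 0.8
    rho_between: float = 0.0
    effect_sizes: tuple[float, ...] = (1.5, 1.0, -1.0, 0.6)
    w1_effect_fraction: float = 0.6
    shift_sigma: float = 1.0
    susceptibility_sigma: float = 0.2
    responder_fraction: float = 0.5
    scfa_link_betas: tuple[float, ...] = (4.0, 2.0, -1.0, 0.0)
    scfa_noise_sigma: float = 1.0
    base_log_sigma: float = 2.0
    baseline_noise_sigma: float = 0.5
    depth: int = 16_000
    n_diet_features: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.guild_sizes) > self.n_otus:
            raise ValueError("guild sizes exceed the number of OTUs")
        if not 0 <= self.rho_between < self.rho_within <= 1:
            raise ValueError("need 0 <= rho_between < rho_within <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.effect_sizes) != len(self.guild_sizes):
            raise ValueError("one effect size per guild required")
        if len(self.scfa_link_betas) != len(self.guild_sizes):
            raise ValueError("one SCFA link beta per guild required")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not 0 < self.n_treatment < self.n_subjects:
            raise ValueError("n_treatment must split the subjects into two arms")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    guild_of: dict[str, str]
    archetype: dict[str, str]
    beta_by_guild: dict[str, float]
    guild_shifts_w6: pd.DataFrame  # subjects x guilds, mean planted CLR shift
    arm_of: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "guild_of": self.guild_of,
            "archetype": self.archetype,
            "beta_by_guild": self.beta_by_guild,
            "guild_shifts_w6": self.guild_shifts_w6.to_dict(orient="index"),
            "arm_of": self.arm_of,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            guild_of=payload["guild_of"],
            archetype=payload["archetype"],
            beta_by_guild=payload["beta_by_guild"],
            guild_shifts_w6=pd.DataFrame.from_dict(
                payload["guild_shifts_w6"], orient="index"
            ),
            arm_of=payload["arm_of"],
        )


@dataclass
class StudyDataset:
    counts: AbundanceTable
    metadata: MetadataTable
    scfa: dict[str, ScfaProfile]
    diaries: dict[str, StoolDiary]
    diet: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_abundance_table(self.counts, outdir / "counts.tsv")
        write_metadata_table(self.metadata, outdir / "metadata.tsv")
        write_scfa_table(self.scfa, outdir / "scfa.tsv")
        write_stool_diary_table(self.diaries, outdir / "stool_diary.tsv")
        diet = self.diet.copy()
        diet.index.name = "subject_id"
        diet.to_csv(outdir / "diet.tsv", sep="\t")
        self.truth.to_json(outdir / "truth.json")


def _guild_labels(cfg: SimConfig) -> list[str]:
    labels: list[str] = []
    for g, size in enumerate(cfg.guild_sizes, start=1):
        labels.extend([f"{GUILD_PREFIX}{g}"] * size)
    labels.extend([BACKGROUND] * (cfg.n_otus - len(labels)))
    return labels


def planted_shift_noise(
    rng: np.random.Generator,
    n_subjects: int,
    guild_labels: list[str],
    rho_within: float,
    rho_between: float,
    sigma: float,
) -> np.ndarray:
    """Zero-mean shift noise with block correlation over guild members.

    Within-guild pairwise correlation equals ``rho_within`` and between-guild
    correlation equals ``rho_between`` via shared subject-level factors;
    background OTUs are independent.
    """
    n_otus = len(guild_labels)
    guilds = [g for g in dict.fromkeys(guild_labels) if g != BACKGROUND]
    common = rng.standard_normal(n_subjects)
    factors = {
        g: np.sqrt(rho_between) * common
        + np.sqrt(1.0 - rho_between) * rng.standard_normal(n_subjects)
        for g in guilds
    }
    noise = np.empty((n_subjects, n_otus))
    for j, lab in enumerate(guild_labels):
        eps = rng.standard_normal(n_subjects)
        if lab == BACKGROUND:
            noise[:, j] = eps
        else:
            noise[:, j] = (
                np.sqrt(rho_within) * factors[lab]
                + np.sqrt(1.0 - rho_within) * eps
            )
    return sigma * noise


def simulate_shift_matrix(
    n_subjects: int = 40,
    guild_sizes: tuple[int, ...] = (10, 10, 10, 10),
    effect_sizes: tuple[float, ...] | None = None,
    rho_within: float = 0.8,
    rho_between: float = 0.0,
    sigma: float = 1.0,
    n_background: int = 0,
    seed: int = 0,
) -> tuple[ShiftMatrix, dict[str, str]]:
    """Directly simulate a CLR shift matrix with planted guild blocks.

    Convenience generator for calibration studies: guild members share a
    mean treatment effect plus correlated noise. Returns the matrix and the
    true OTU -> guild labels.
    """
    if effect_sizes is None:
        effect_sizes = tuple(2.0 if g % 2 == 0 else -2.0 for g in range(len(guild_sizes)))
    rng = np.random.default_rng(seed)
    labels = []
    means = []
    for g, (size, eff) in enumerate(zip(guild_sizes, effect_sizes), start=1):
        labels.extend([f"{GUILD_PREFIX}{g}"] * size)
        means.extend([eff] * size)
    labels.extend([BACKGROUND] * n_background)
    means.extend([0.0] * n_background)
    noise = planted_shift_noise(rng, n_subjects, labels, rho_within, rho_between, sigma)
    values = np.asarray(means)[None, :] + noise
    otu_ids = [f"OTU{j + 1:03d}" for j in range(len(labels))]
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    truth = dict(zip(otu_ids, labels))
    return ShiftMatrix(subject_ids, otu_ids, values), truth


def generate_study(cfg: SimConfig) -> StudyDataset:
    """Generate a complete synthetic two-arm intervention dataset."""
    rng = np.random.default_rng(cfg.seed)
    design = StudyDesign()
    n = cfg.n_subjects
    subjects = [f"S{i + 1:02d}" for i in range(n)]
    arms = ["AX"] * cfg.n_treatment + ["MCC"] * (n - cfg.n_treatment)
    n_female = int(round(cfg.female_fraction * n))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    rng.shuffle(sexes)
    otu_ids = [f"OTU{j + 1:03d}" for j in range(cfg.n_otus)]
    guild_labels = _guild_labels(cfg)
    guilds = [g for g in dict.fromkeys(guild_labels) if g != BACKGROUND]

    # log-normal baseline abundance spectrum + per-subject noise
    base_log = rng.normal(0.0, cfg.base_log_sigma, size=cfg.n_otus)
    baseline_log = base_log[None, :] + rng.normal(
        0.0, cfg.baseline_noise_sigma, size=(n, cfg.n_otus)
    )

    susceptibility = np.exp(rng.normal(0.0, cfg.susceptibility_sigma, size=n))
    effect_by_otu = np.array(
        [
            cfg.effect_sizes[guilds.index(lab)] if lab != BACKGROUND else 0.0
            for lab in guild_labels
        ]
    )
    treated = np.array([a == "AX" for a in arms])
    shifts: dict[str, np.ndarray] = {}
    for tp, frac in (("W1", cfg.w1_effect_fraction), ("W6", 1.0)):
        noise = planted_shift_noise(
            rng, n, guild_labels, cfg.rho_within, cfg.rho_between, cfg.shift_sigma
        )
        planted = frac * effect_by_otu[None, :] * susceptibility[:, None]
        planted = planted * treated[:, None]
        shifts[tp] = planted + noise

    sample_ids: list[str] = []
    meta_records: list[SampleMetadata] = []
    count_rows: list[np.ndarray] = []
    for tp in ("BL", "W1", "W6"):
        for i, subject in enumerate(subjects):
            sid = f"{subject}_{tp}"
            sample_ids.append(sid)
            meta_records.append(
                SampleMetadata(
                    sample_id=sid,
                    subject_id=subject,
                    arm=arms[i],
                    sex=sexes[i],
                    dose=design.full_dose(sexes[i]),
                    timepoint=tp,
                )
            )
            logs = baseline_log[i] + (shifts[tp][i] if tp != "BL" else 0.0)
            p = np.exp(logs - logs.max())
            p /= p.sum()
            count_rows.append(rng.multinomial(cfg.depth, p).astype(float))
    counts = AbundanceTable(sample_ids, otu_ids, np.vstack(count_rows), "counts")
    metadata = MetadataTable(meta_records, design=design)

    # mean planted CLR shift per guild per subject (the linkable truth)
    guild_shifts = pd.DataFrame(index=subjects, columns=guilds, dtype=float)
    for g, lab in enumerate(guilds):
        idx = [j for j, lj in enumerate(guild_labels) if lj == lab]
        guild_shifts[lab] = shifts["W6"][:, idx].mean(axis=1)

    n_resp = int(round(cfg.responder_fraction * n))
    archetypes = [RESPONDER] * n_resp + [NONRESPONDER] * (n - n_resp)
    rng.shuffle(archetypes)

    betas = dict(zip(guilds, cfg.scfa_link_betas))
    scfa: dict[str, ScfaProfile] = {}
    for i, subject in enumerate(subjects):
        prop_bl = max(0.5, rng.normal(15.0, 3.0))
        total_delta = float(
            sum(betas[g] * guild_shifts.loc[subject, g] for g in guilds)
            + rng.normal(0.0, cfg.scfa_noise_sigma)
        )
        prop_w6 = max(0.1, prop_bl + total_delta)
        gap = abs(rng.normal(0.0, 1.0)) + 0.25
        if archetypes[i] == RESPONDER:
            prop_w1 = max(0.05, prop_w6 - gap)
        else:
            prop_w1 = prop_w6 + gap
        ace_bl = max(1.0, rng.normal(45.0, 8.0))
        but_bl = max(0.5, rng.normal(12.0, 3.0))
        props = {"BL": prop_bl, "W1": prop_w1, "W6": prop_w6}
        for tp in ("BL", "W1", "W6"):
            ace = max(0.5, ace_bl + 0.3 * (props[tp] - prop_bl) + rng.normal(0, 2.0))
            but = max(0.1, but_bl + 0.1 * (props[tp] - prop_bl) + rng.normal(0, 1.0))
            sid = f"{subject}_{tp}"
            scfa[sid] = ScfaProfile(
                sample_id=sid,
                acetate=ace,
                propionate=props[tp],
                butyrate=but,
                isobutyrate=max(0.05, rng.normal(1.5, 0.4)),
                isovalerate=max(0.05, rng.normal(2.0, 0.5)),
                ph=float(np.clip(rng.normal(6.5, 0.4), 5.0, 8.0)),
                moisture=float(np.clip(rng.normal(0.72, 0.05), 0.4, 0.95)),
            )

    diaries: dict[str, StoolDiary] = {}
    for subject in subjects:
        cons = np.clip(np.round(rng.normal(2.0, 0.8, size=7)), 0, 4)
        freq = np.clip(np.round(rng.normal(2.0, 0.8, size=7)), 0, 4)
        diaries[subject] = StoolDiary(subject, tuple(cons), tuple(freq))

    # correlated Gaussian diet block
    k = cfg.n_diet_features
    shared = rng.standard_normal((n, 1))
    diet_vals = 0.5 * shared + rng.standard_normal((n, k))
    diet = pd.DataFrame(
        diet_vals, index=subjects, columns=[f"diet{j + 1}" for j in range(k)]
    )

    truth = GroundTruth(
        guild_of=dict(zip(otu_ids, guild_labels)),
        archetype=dict(zip(subjects, archetypes)),
        beta_by_guild=betas,
        guild_shifts_w6=guild_shifts,
        arm_of=dict(zip(subjects, arms)),
    )
    return StudyDataset(counts, metadata, scfa, diaries, diet, truth)


def evaluate_guild_recovery(truth_labels: dict[str, str], assignment) -> float:
    """Adjusted Rand Index between planted guilds and a recovered partition."""
    from sklearn.metrics import adjusted_rand_score

    common = [o for o in assignment.labels if o in truth_labels]
    if not common:
        raise ValueError("assignment and truth share no OTUs")
    return float(
        adjusted_rand_score(
            [truth_labels[o] for o in common],
            [assignment.labels[o] for o in common],
        )
    )


def evaluate_prediction_recovery(
    screen, planted_block: str, response: str = "propionate"
) -> dict[str, object]:
    """Did the screen flag the planted block for the given response?

    Reports whether the planted block's cell reached q < 0.05 and whether it
    achieved the lowest relative AICc among that response's cells.
    """
    cells = [c for c in screen.cells if c.response == response]
    if not cells:
        return {"selected": False, "lowest_rel_aicc": False, "q": None}
    try:
        cell = screen.cell(response, planted_block)
    except KeyError:
        return {"selected": False, "lowest_rel_aicc": False, "q": None}
    best = min(cells, key=lambda c: c.rel_aicc if c.rel_aicc is not None else np.inf)
    return {
        "selected": cell.q is not None and cell.q < 0.05,
        "lowest_rel_aicc": best.block == planted_block,
        "q": cell.q,
    }
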