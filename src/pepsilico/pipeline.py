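"""Orchestration: digest -> profile -> physchem -> drug-likeness (-> affinity).

One reproducible run over a validated configuration. Every stage writes a
TSV into the run directory and a JSON manifest records the configuration,
input digests and package version; identical configuration yields
byte-identical outputs (timestamps only ever go to the log).

The screening step consumes prediction-score annotation columns (general
bioactivity and per-activity scores produced by external ML screens); a
peptide passes the general screen at >= 0.7 and is flagged for an activity
at >= 0.5. Scores printed as "-" (below the reporting threshold) count as
below threshold. Because several candidates carry both antihypertensive and
antidiabetic flags, peptides are also assigned to a single exclusive target
group - DPPIV/antidiabetic taking precedence over ACE/antihypertensive,
matching how dual-flagged candidates are carried forward to the antidiabetic
target in the published screen - while the raw per-activity flags stay
reported side by side.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bioactivity_profile import profile_table
from .digestion import default_rules, digest_all, digest_table, load_rule_table
from .druglikeness import peptide_descriptors
from .io_formats import read_bioactivity_table, read_fasta, read_pdb_complex, write_tsv
from .physchem import physchem_report
from .synthetic_data import candidate_peptides

logger = logging.getLogger(__name__)

GENERAL_THRESHOLD = 0.7
SPECIFIC_THRESHOLD = 0.5

ACTIVITY_COLUMNS = (
    "ace_inhibitory", "antihypertensive", "antidiabetic", "dppiv_inhibitory",
)


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    rules: str | None = None  # TSV path; None = shipped defaults
    enzymes: list[str] = field(default_factory=lambda: ["ficin", "papain", "bromelain"])
    min_length: int = 3
    motif_db: str | None = None
    activities: list[str] = field(default_factory=list)
    scores: str | None = None  # peptide score-annotation TSV
    general_threshold: float = GENERAL_THRESHOLD
    specific_threshold: float = SPECIFIC_THRESHOLD
    mass_mode: str = "monoisotopic"
    ro5_mode: str = "lipinski4"
    pdb: str | None = None
    group_a: list[str] = field(default_factory=lambda: ["A"])
    group_b: list[str] = field(default_factory=lambda: ["B"])
    cutoff: float = 5.5
    rsa_threshold: float = 0.05
    temperature: float = 298.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        for threshold in (self.general_threshold, self.specific_threshold):
            if not 0.0 <= threshold <= 1.0:
                raise ValueError("score thresholds must lie in [0, 1]")
        for path in (self.fasta, self.rules, self.motif_db, self.scores, self.pdb):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _coerce_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Turn "-" (and blanks) into NaN and score columns into floats."""
    df = df.copy()
    for col in df.columns:
        if col == "sequence":
            continue
        df[col] = pd.to_numeric(
            df[col].replace({"-": None, "−": None, "": None}), errors="raise"
        )
    return df


def screen_by_scores(
    peptides: pd.DataFrame,
    general_threshold: float = GENERAL_THRESHOLD,
    specific_threshold: float = SPECIFIC_THRESHOLD,
) -> pd.DataFrame:
    """Filter and flag peptides by their prediction-score annotations.

    Input columns: ``sequence``, optional ``general_score``, and any of the
    per-activity columns (``ace_inhibitory``, ``antihypertensive``,
    ``antidiabetic``, ``dppiv_inhibitory``). Returns the retained peptides
    with boolean activity flags, merged-group flags and the exclusive
    ``target_group`` assignment (ACE, DPPIV or unassigned).
    """
    df = _coerce_scores(peptides)
    if "general_score" in df.columns:
        df = df[df["general_score"] >= general_threshold].copy()
    for col in ACTIVITY_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
        df[f"flag_{col}"] = df[col].ge(specific_threshold).fillna(False)
    df["flag_ace_or_antihypertensive"] = (
        df["flag_ace_inhibitory"] | df["flag_antihypertensive"]
    )
    df["flag_dppiv_or_antidiabetic"] = (
        df["flag_dppiv_inhibitory"] | df["flag_antidiabetic"]
    )
    df["target_group"] = "unassigned"
    df.loc[df["flag_ace_or_antihypertensive"], "target_group"] = "ACE"
    # antidiabetic/DPPIV flags take precedence for dual-flagged peptides
    df.loc[df["flag_dppiv_or_antidiabetic"], "target_group"] = "DPPIV"
    return df.reset_index(drop=True)


def fixture_score_frame() -> pd.DataFrame:
    """The twelve screened candidate peptides as a score-annotation table."""
    rows = [
        {
            "sequence": p.sequence,
            "ace_inhibitory": p.ace_inhibitory,
            "antihypertensive": p.antihypertensive,
            "antidiabetic": p.antidiabetic,
            "dppiv_inhibitory": p.dppiv_inhibitory,
        }
        for p in candidate_peptides()
    ]
    return pd.DataFrame(rows)


def druglikeness_table(sequences: list[str], mode: str = "lipinski4") -> pd.DataFrame:
    rows = []
    for seq in sequences:
        d = peptide_descriptors(seq, mode=mode)
        row = {
            "sequence": d.sequence,
            "formula": d.formula,
            "mw_mono": d.mw_monoisotopic,
            "hba": d.hba,
            "hbd": d.hbd,
            "logp_est": d.logp_estimate,
            "tpsa_est": d.tpsa_estimate,
            "ro5_violations": d.ro5_violations,
        }
        row.update({f"pass_{k}": v for k, v in d.ro5_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def physchem_table(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        report = physchem_report(rec.id, rec.sequence)
        row = {
            "id": report.id,
            "length": report.length,
            "mw_average": report.mw_average,
            "mw_monoisotopic": report.mw_monoisotopic,
            "neg_residues": report.neg_residues,
            "pos_residues": report.pos_residues,
            "pi": report.pi,
            "gravy": report.gravy,
            "aliphatic_index": report.aliphatic_index,
            "instability_index": report.instability_index,
            "stability_class": report.stability_class,
            "extinction_oxidized": report.extinction_oxidized,
            "extinction_reduced": report.extinction_reduced,
        }
        row.update({f"frac_{k}": v for k, v in report.aa_class_distribution.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage in order; returns the run directory.

    Any stage error aborts the run with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "pepsilico",
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": [],
    }
    for label in ("fasta", "rules", "motif_db", "scores", "pdb"):
        path = getattr(config, label)
        if path is not None:
            manifest["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}

    stage = "read_fasta"
    try:
        proteins = read_fasta(config.fasta)

        stage = "digest"
        rules_by_name = (
            load_rule_table(config.rules) if config.rules else default_rules()
        )
        missing = [e for e in config.enzymes if e not in rules_by_name]
        if missing:
            raise ValueError(f"enzymes not in rule table: {missing}")
        rules = [rules_by_name[e] for e in config.enzymes]
        results = digest_all(proteins, rules, min_length=config.min_length)
        write_tsv(digest_table(results), out / "digest.tsv")
        manifest["stages"].append({"name": "digest", "rows": len(results),
                                   "min_length": config.min_length})

        if config.motif_db and config.activities:
            stage = "profile"
            db = read_bioactivity_table(config.motif_db)
            profile = profile_table(proteins, rules, db, config.activities,
                                    min_length=config.min_length)
            write_tsv(profile, out / "profile.tsv")
            manifest["stages"].append({"name": "profile", "rows": len(profile),
                                       "activities": list(config.activities)})

        stage = "physchem"
        write_tsv(physchem_table(proteins), out / "physchem.tsv")
        manifest["stages"].append({"name": "physchem", "rows": len(proteins)})

        stage = "druglikeness"
        peptide_pool = sorted({seq for r in results for seq in r.retained_sequences})
        if config.scores:
            scores = pd.read_csv(config.scores, sep="\t", dtype=str)
            screened = screen_by_scores(
                scores, config.general_threshold, config.specific_threshold
            )
            write_tsv(screened, out / "screen.tsv")
            manifest["stages"].append({
                "name": "screen",
                "rows": len(screened),
                "general_threshold": config.general_threshold,
                "specific_threshold": config.specific_threshold,
            })
            peptide_pool = list(screened["sequence"])
        write_tsv(druglikeness_table(peptide_pool, mode=config.ro5_mode),
                  out / "druglike.tsv")
        manifest["stages"].append({"name": "druglikeness", "rows": len(peptide_pool),
                                   "ro5_mode": config.ro5_mode})

        if config.pdb:
            stage = "affinity"
            from .affinity import analyse_complex

            complex_ = read_pdb_complex(config.pdb, config.group_a, config.group_b)
            stats, result = analyse_complex(
                complex_, cutoff=config.cutoff,
                rsa_threshold=config.rsa_threshold,
                temperature=config.temperature,
            )
            affinity_df = pd.DataFrame([{
                "ic_charged_charged": stats.ic_charged_charged,
                "ic_charged_apolar": stats.ic_charged_apolar,
                "ic_charged_polar": stats.ic_charged_polar,
                "ic_polar_polar": stats.ic_polar_polar,
                "ic_polar_apolar": stats.ic_polar_apolar,
                "ic_apolar_apolar": stats.ic_apolar_apolar,
                "nis_apolar_percent": stats.nis_apolar_percent,
                "nis_charged_percent": stats.nis_charged_percent,
                "nis_polar_percent": stats.nis_polar_percent,
                "cutoff": stats.cutoff,
                "rsa_threshold": stats.rsa_threshold,
                "dg_kcal_mol": result.dg,
                "kd_molar": result.kd,
                "temperature_k": result.temperature,
            }])
            write_tsv(affinity_df, out / "affinity.tsv", float_decimals=4)
            manifest["stages"].append({"name": "affinity",
                                       "cutoff": config.cutoff,
                                       "rsa_threshold": config.rsa_threshold,
                                       "temperature": config.temperature})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline run complete: %s", out)
    return out
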