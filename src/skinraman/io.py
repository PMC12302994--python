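"""Plain-text readers/writers and run configuration.

All artifacts are delimited text or key-value YAML: spectra as long-format
CSV (spectrum_id, replicate_index, wavenumber, intensity), the cohort
manifest as CSV, processed features as a matrix CSV with a channel-map
sidecar, attention maps as (wavenumber, score) CSV per class.  Every
artifact embeds the hash of the run configuration that produced it as a
``# config_hash=...`` comment line, so a report directory is traceable to
its configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attention import OcclusionConfig
from .models import TrainingConfig
from .preprocess import PreprocessConfig, ProcessedDataset, SpectralRange
from .spectra import RamanSpectrum, SpectralDataset
from .synth import CohortConfig

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_spectra",
    "read_features",
    "write_features",
    "write_attention_maps",
    "write_text",
]

_SPECTRA_COLUMNS = ["spectrum_id", "replicate_index", "wavenumber", "intensity"]
_MANIFEST_COLUMNS = ["spectrum_id", "patient_id", "lesion", "target", "replicate_index"]


def _hash_line(config_hash: str | None) -> str:
    return f"# config_hash={config_hash or 'none'}\n"


def write_text(path: str | Path, text: str, config_hash: str | None = None) -> None:
    Path(path).write_text(_hash_line(config_hash) + text)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str | None) -> None:
    with open(path, "w") as fh:
        fh.write(_hash_line(config_hash))
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # propagate with file identity
        raise ValueError(f"{path}: malformed delimited text ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_spectra(
    dataset: SpectralDataset, out_dir: str | Path, config_hash: str | None = None
) -> Path:
    """Write a dataset as spectra.csv + manifest.csv (+ dark.csv, meta.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset:
        rows.append(
            pd.DataFrame(
                {
                    "spectrum_id": s.spectrum_id,
                    "replicate_index": str(s.replicate_index),
                    "wavenumber": s.wavenumbers,
                    "intensity": s.intensities,
                }
            )
        )
    _write_csv(pd.concat(rows, ignore_index=True), out / "spectra.csv", config_hash)
    _write_csv(dataset.manifest, out / "manifest.csv", config_hash)
    if dataset.dark is not None:
        _write_csv(
            pd.DataFrame(
                {
                    "wavenumber": dataset.dark.wavenumbers,
                    "intensity": dataset.dark.intensities,
                }
            ),
            out / "dark.csv",
            config_hash,
        )
    meta = dict(dataset.metadata)
    meta["config_hash"] = config_hash or "none"
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_spectra(path: str | Path) -> SpectralDataset:
    """Read a dataset written by :func:`write_spectra`.

    Malformed numeric values are reported with their (1-based, post-header)
    row numbers.
    """
    path = Path(path)
    spectra_df = _read_csv(path / "spectra.csv", _SPECTRA_COLUMNS)
    manifest = _read_csv(path / "manifest.csv", _MANIFEST_COLUMNS)
    for col in ("wavenumber", "intensity"):
        vals = pd.to_numeric(spectra_df[col], errors="coerce")
        bad = spectra_df.index[vals.isna() & spectra_df[col].notna()]
        if len(bad):
            raise ValueError(
                f"spectra.csv: non-numeric {col} at row(s) {list(bad[:5] + 1)}"
            )
        spectra_df[col] = vals
    meta_path = path / "meta.yaml"
    metadata = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    dark = None
    if (path / "dark.csv").exists():
        dark_df = _read_csv(path / "dark.csv", ["wavenumber", "intensity"])
        dark = RamanSpectrum(
            dark_df["wavenumber"].to_numpy(),
            dark_df["intensity"].to_numpy(),
            spectrum_id="dark",
            replicate_index=0,
        )

    meta_rows = {
        (str(r.spectrum_id), str(r.replicate_index)): r
        for r in manifest.itertuples()
    }
    spectra = []
    for (sid, rep), group in spectra_df.groupby(
        ["spectrum_id", "replicate_index"], sort=False
    ):
        key = (str(sid), str(rep))
        if key not in meta_rows:
            raise ValueError(f"spectrum {key} present in spectra.csv but not manifest.csv")
        m = meta_rows[key]
        group = group.sort_values("wavenumber")
        spectra.append(
            RamanSpectrum(
                group["wavenumber"].to_numpy(),
                group["intensity"].to_numpy(),
                spectrum_id=str(sid),
                patient_id=str(m.patient_id),
                lesion=None if pd.isna(m.lesion) else str(m.lesion),
                target=None if pd.isna(m.target) else str(m.target),
                replicate_index="mean" if str(rep) == "mean" else int(rep),
            )
        )
    return SpectralDataset(spectra, dark=dark, metadata=metadata or {})


def write_features(
    processed: ProcessedDataset, out_dir: str | Path, config_hash: str | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feat = pd.DataFrame(
        processed.features,
        columns=[f"ch{i:04d}" for i in range(processed.features.shape[1])],
    )
    feat.insert(0, "spectrum_id", processed.manifest["spectrum_id"].to_numpy())
    _write_csv(feat, out / "features.csv", config_hash)
    _write_csv(processed.channel_map, out / "channel_map.csv", config_hash)
    _write_csv(processed.manifest, out / "feature_manifest.csv", config_hash)
    return out


def read_features(path: str | Path) -> ProcessedDataset:
    path = Path(path)
    feat = _read_csv(path / "features.csv", ["spectrum_id"])
    channel_map = _read_csv(path / "channel_map.csv", ["range_index", "wavenumber"])
    manifest = _read_csv(path / "feature_manifest.csv", _MANIFEST_COLUMNS)
    features = feat.drop(columns=["spectrum_id"]).to_numpy(dtype=float)
    return ProcessedDataset(features=features, channel_map=channel_map, manifest=manifest)


def write_attention_maps(
    maps: dict, wavenumbers, out_dir: str | Path,
    consistency: dict | None = None, config_hash: str | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cls, amap in maps.items():
        _write_csv(
            pd.DataFrame({"wavenumber": wavenumbers, "score": amap.scores}),
            out / f"attention_{cls}.csv",
            config_hash,
        )
    if consistency is not None:
        lines = [f"{cls}: {val:.6f}" for cls, val in consistency.items()]
        write_text(out / "fold_consistency.txt", "\n".join(lines) + "\n", config_hash)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (simulate -> preprocess ->
    cross-validate -> attention -> biochem)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    occlusion: OcclusionConfig = field(default_factory=OcclusionConfig)
    model_kinds: tuple[str, ...] = ("cnn",)
    class_setups: tuple[int, ...] = (4, 5)
    k: int = 5
    seed: int = 0
    planted_effects: bool = True
    run_attention: bool = True
    run_biochem: bool = True

    @classmethod
    def smoke(cls, seed: int = 0, n_patients_per_lesion: int = 10) -> "RunConfig":
        """Small deterministic end-to-end run for tests and demos."""
        return cls(
            cohort=CohortConfig.small(n_patients_per_lesion, seed=seed),
            training=TrainingConfig(epochs=40, seed=seed),
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = {
            "cohort": asdict(self.cohort),
            "preprocess": asdict(self.preprocess),
            "training": asdict(self.training),
            "occlusion": asdict(self.occlusion),
            "model_kinds": list(self.model_kinds),
            "class_setups": list(self.class_setups),
            "k": self.k,
            "seed": self.seed,
            "planted_effects": self.planted_effects,
            "run_attention": self.run_attention,
            "run_biochem": self.run_biochem,
        }
        # YAML-safe keys for the (lesion, target) count map
        d["cohort"]["spectra_per_target"] = {
            f"{lesion}/{target}": n
            for (lesion, target), n in self.cohort.spectra_per_target.items()
        }
        d["preprocess"]["ranges"] = [asdict(r) for r in self.preprocess.ranges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = dict(d["cohort"])
        cohort["spectra_per_target"] = {
            tuple(key.split("/")): n
            for key, n in cohort["spectra_per_target"].items()
        }
        pp = dict(d["preprocess"])
        pp["ranges"] = tuple(SpectralRange(**r) for r in pp["ranges"])
        return cls(
            cohort=CohortConfig(**cohort),
            preprocess=PreprocessConfig(**pp),
            training=TrainingConfig(**d["training"]),
            occlusion=OcclusionConfig(**d["occlusion"]),
            model_kinds=tuple(d["model_kinds"]),
            class_setups=tuple(d["class_setups"]),
            k=d["k"],
            seed=d["seed"],
            planted_effects=d["planted_effects"],
            run_attention=d["run_attention"],
            run_biochem=d["run_biochem"],
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
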