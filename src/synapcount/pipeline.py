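"""End-to-end orchestration: simulate -> detect -> count -> calibrate -> extrapolate.

`run_calibration` reproduces the two-microscope workflow on synthetic
tissue: per layer it renders SDM-like fields and FIB-SEM-like volumes from
one set of ground-truth densities, measures puncta densities and the
colocalization index on the 2D side, counts AS/SS synapses in unbiased
bricks on the 3D side, and forms per-layer and averaged conversion factors.
`run_brainwide` applies a conversion factor to a per-region puncta density
table, producing flagged minimum synapse-density estimates.

Every stochastic stage derives its seed deterministically from the global
seed plus the stage name, so identical configs give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import densify, emstack, puncta, refdata, synthgen


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the global seed."""
    mix = np.random.SeedSequence([int(global_seed),
                                  zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2 ** 31))


def _default_layers() -> dict:
    """Per-layer study conditions mirroring the CA1 reference magnitudes."""
    layers = {}
    for row in refdata.CA1_LAYER_SUMMARY.itertuples():
        if row.layer == "all":
            continue
        layers[row.layer] = {
            "density_ch1": row.dPSD95,
            "density_ch2": row.dSAP102,
            "coloc_fraction": row.c,
            "as_density": row.as_density,
            # overall SS share is ~4.4% of all synapses
            "ss_density": round(row.as_density * 0.046, 4),
        }
    return layers


@dataclass
class RunConfig:
    """Configuration of a calibration run (YAML-serializable)."""

    seed: int = 0
    layers: dict = field(default_factory=_default_layers)
    n_fields_per_layer: int = 2
    n_stacks_per_layer: int = 5
    field_width_um: float = 43.008
    field_height_um: float = 43.008
    pixel_size_nm: float = 84.0
    em_dims_um: tuple[float, float, float] = (5.12, 3.84, 2.4)
    em_voxel_nm: tuple[float, float, float] = (5.0, 5.0, 20.0)
    frame_margin_um: float = 0.25
    shrinkage_linear: float = 1.0     # synthetic tissue never shrank
    correct_shrinkage: bool = True
    ratio_threshold: float = 1.5
    averaging_mode: str = "mean_of_layers"
    outdir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "em_dims_um" in data:
            data["em_dims_um"] = tuple(data["em_dims_um"])
        if "em_voxel_nm" in data:
            data["em_voxel_nm"] = tuple(data["em_voxel_nm"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(
            yaml.safe_dump(json.loads(json.dumps(asdict(self),
                                                 default=list))))


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def train_default_classifier(seed: int, spec: synthgen.PunctaFieldSpec | None = None,
                             n_fields: int = 2):
    """Train the punctum/background classifier on synthetic fields.

    Candidates are harvested at the low detection threshold from freshly
    rendered fields and labeled true iff they fall within 2 px of a
    ground-truth punctum of the same channel.
    """
    from scipy.spatial import cKDTree

    base = spec or synthgen.PunctaFieldSpec()
    cands, labels = [], []
    for i in range(n_fields):
        fspec = synthgen.PunctaFieldSpec(
            **{**_spec_dict(base), "seed": stage_seed(seed, f"train-{i}")})
        image, truth = synthgen.make_puncta_field(fspec)
        for ch in (1, 2):
            cc = puncta.detect_candidates(image[ch - 1], channel=ch)
            gt = truth[truth.channel == ch][["y_px", "x_px"]].to_numpy()
            if len(gt):
                tree = cKDTree(gt)
                for cand in cc:
                    d, _ = tree.query(cand.peak)
                    labels.append(d <= 2.0)
            else:
                labels.extend([False] * len(cc))
            cands.extend(cc)
    return puncta.train_classifier(cands, labels, seed=seed)


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return d


# --------------------------------------------------------------------------

def run_calibration(config: RunConfig, write: bool = True) -> dict:
    """Full synthetic calibration; returns (and optionally writes) the report."""
    factors = emstack.shrinkage_from_linear(config.shrinkage_linear)
    try:
        classifier = train_default_classifier(
            stage_seed(config.seed, "classifier"),
            synthgen.PunctaFieldSpec(
                field_width=config.field_width_um,
                field_height=config.field_height_um,
                pixel_size=config.pixel_size_nm))
    except Exception as exc:          # noqa: BLE001 - stage-tagged abort
        raise StageError(f"[classifier] {exc}") from exc

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "shrinkage": {"linear": factors.linear, "area": factors.area,
                      "volume": factors.volume,
                      "direction": "measured / factor (shrunken tissue "
                                   "re-expanded to in-vivo scale)"},
        "layers": {},
    }

    layer_records, layer_as, layer_k_true = [], [], []
    for layer, pars in config.layers.items():
        # ---- SDM side -----------------------------------------------------
        per_field = []
        try:
            for i in range(config.n_fields_per_layer):
                fspec = synthgen.PunctaFieldSpec(
                    field_width=config.field_width_um,
                    field_height=config.field_height_um,
                    pixel_size=config.pixel_size_nm,
                    density_ch1=pars["density_ch1"],
                    density_ch2=pars["density_ch2"],
                    coloc_fraction=pars["coloc_fraction"],
                    seed=stage_seed(config.seed, f"sdm-{layer}-{i}"))
                image, _ = synthgen.make_puncta_field(fspec)
                _, _, summary = puncta.analyze_field(
                    image, classifier, fspec.area_um2,
                    pixel_size=config.pixel_size_nm)
                if summary["n_ch1"] + summary["n_ch2"] > 0:
                    per_field.append(densify.total_density(
                        summary["d_ch1"], summary["d_ch2"], summary["c"],
                        unit=f"{layer}-field{i}"))
        except Exception as exc:      # noqa: BLE001
            raise StageError(f"[sdm:{layer}] {exc}") from exc

        # ---- FIB-SEM side -------------------------------------------------
        stack_densities = []
        try:
            for i in range(config.n_stacks_per_layer):
                espec = synthgen.EmVolumeSpec(
                    dims=config.em_dims_um, voxel_size=config.em_voxel_nm,
                    as_density=pars["as_density"],
                    ss_density=pars["ss_density"],
                    seed=stage_seed(config.seed, f"em-{layer}-{i}"))
                labels, truth = synthgen.make_em_volume(espec)
                if len(truth) == 0:
                    continue
                records = emstack.records_from_labels(
                    labels, synthgen.label_map(truth),
                    voxel_size=config.em_voxel_nm, factors=factors,
                    ratio_threshold=config.ratio_threshold)
                m = config.frame_margin_um
                frame = emstack.CountingFrame(
                    origin=(m, m, m),
                    extent=tuple(d - 2 * m for d in config.em_dims_um))
                counted = set(emstack.count_in_frame(
                    records, frame, volume_bounds=config.em_dims_um))
                by_id = {r.id: r for r in records}
                n_as = sum(1 for cid in counted if by_id[cid].type == "AS")
                n_ss = len(counted) - n_as
                stack_densities.append(emstack.synapse_density(
                    n_as, n_ss, frame.volume, factors,
                    sample_id=f"{layer}-stack{i}",
                    correct=config.correct_shrinkage))
        except Exception as exc:      # noqa: BLE001
            raise StageError(f"[em:{layer}] {exc}") from exc

        layer_mean = {
            "dPSD95": float(np.mean([r.dPSD95 for r in per_field])) if per_field else 0.0,
            "dSAP102": float(np.mean([r.dSAP102 for r in per_field])) if per_field else 0.0,
            "c": float(np.mean([r.c for r in per_field])) if per_field else 0.0,
            "dTotal": float(np.mean([r.dTotal for r in per_field])) if per_field else 0.0,
            "as_density": float(np.mean([s.density_as for s in stack_densities])) if stack_densities else 0.0,
            "ss_density": float(np.mean([s.density_ss for s in stack_densities])) if stack_densities else 0.0,
        }
        d_true = (pars["density_ch1"] + pars["density_ch2"]) / \
            (1.0 + pars["coloc_fraction"]) if pars["coloc_fraction"] >= 0 else 0.0
        k_layer = (layer_mean["as_density"] / layer_mean["dTotal"]
                   if layer_mean["dTotal"] > 0 else None)
        k_true = pars["as_density"] / d_true if d_true > 0 else None
        report["layers"][layer] = {
            "per_field": [asdict(r) for r in per_field],
            "per_stack": [asdict(s) for s in stack_densities],
            "means": layer_mean,
            "conversion_factor": k_layer,
            "true": {"dTotal": d_true, "as_density": pars["as_density"],
                     "conversion_factor": k_true},
        }
        if k_layer is not None:
            layer_records.append(densify.total_density(
                layer_mean["dPSD95"], layer_mean["dSAP102"], layer_mean["c"],
                unit=layer))
            layer_as.append(layer_mean["as_density"])
        if k_true is not None:
            layer_k_true.append(k_true)

    if layer_records:
        avg = densify.averaged_conversion_factor(
            layer_records, layer_as, mode=config.averaging_mode)
        report["averaged_conversion_factor"] = avg.k
    else:
        report["averaged_conversion_factor"] = None
    report["true_averaged_conversion_factor"] = (
        float(np.mean(layer_k_true)) if layer_k_true else None)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "calibration.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_brainwide(region_table: pd.DataFrame, k: float | None = None,
                  calibration: dict | None = None,
                  out_path=None) -> pd.DataFrame:
    """Apply a conversion factor to a region table of puncta densities.

    ``k`` may be given directly or taken from a calibration report.  The
    result is sorted by estimate, descending, and flagged as minimum
    estimates (unlabeled synapses are invisible to the 2D readout).
    """
    if k is None and calibration is not None:
        k = calibration.get("averaged_conversion_factor")
    if k is None:
        raise StageError("[brainwide] no conversion factor available")
    factor = densify.ConversionFactor(k=float(k), scope="averaged")
    estimates = densify.apply_conversion(region_table, factor)
    df = densify.estimates_to_frame(estimates)
    df = df.sort_values("est_density", ascending=False,
                        kind="mergesort").reset_index(drop=True)
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("# minimum synapse-density estimates: "
                     f"k={factor.k:.6g} per (puncta/100um^2)\n")
            df.to_csv(fh, index=False)
    return df
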