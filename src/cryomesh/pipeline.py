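"""Per-scene analysis and cross-genotype report assembly.

``analyze_scene`` runs every applicable analysis stage on one scene and
returns tidy tables; ``build_genotype_report`` pools analyzed scenes by
genotype and adds the statistical comparisons.  Both are deterministic
given the scene content and the run configuration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .compare import compare_angle_distributions, compare_scalars_anova, circular_spread
from .config import RunConfig
from .filaments import angles_to_mean, fragment_filaments, mean_orientation, radial_profile
from .io import Compartment, MaskLabel, Scene
from .shape import nucleoid_width, principal_shape
from .spatial import (
    exclusion_report,
    mask_to_mask_distances,
    mask_to_membrane_distance,
    nearest_neighbor_distances,
)

__all__ = ["analyze_scene", "build_genotype_report"]

ABSENT = "absent"


def _fragment_table(scene: Scene, config: RunConfig):
    """Per-fragment tidy rows plus per-compartment angle samples."""
    rows = []
    angle_samples = {}
    for comp in (Compartment.assembly, Compartment.nucleoid):
        fils = scene.filaments_in(comp)
        if not fils:
            continue
        frags = fragment_filaments(fils, config.fragment_length)
        if len(frags) < 1:
            warnings.warn(f"{comp.value}: no fragments at L={config.fragment_length} nm")
            continue
        mean = mean_orientation(frags)
        dist = angles_to_mean(frags, mean, bin_width=config.bin_width)
        angle_samples[comp.value] = dist
        center = frags.midpoints.mean(axis=0)
        r = np.linalg.norm(frags.midpoints - center, axis=1)
        rows.append(pd.DataFrame({
            "compartment": comp.value,
            "source_id": frags.source_ids,
            "theta_deg": dist.angles,
            "mid_x": frags.midpoints[:, 0],
            "mid_y": frags.midpoints[:, 1],
            "mid_z": frags.midpoints[:, 2],
            "r_to_center": r,
        }))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["compartment", "source_id", "theta_deg", "mid_x", "mid_y",
                 "mid_z", "r_to_center"])
    return df, angle_samples


def analyze_scene(scene: Scene, config: RunConfig | None = None) -> dict:
    """Run all analysis stages on one scene; returns named tidy tables.

    Stages whose inputs are missing from the scene are reported as
    ``absent`` in the summary rather than failing.
    """
    config = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}
    summary: list[tuple[str, object]] = [
        ("config_hash", config.hash),
        ("genotype", scene.meta.genotype.value),
        ("seed", scene.meta.seed if scene.meta.seed is not None else ABSENT),
        ("fragment_length_nm", config.fragment_length),
        ("bin_width_deg", config.bin_width),
        ("peak_method", config.peak_method),
        ("contact_threshold_nm", config.contact_threshold),
    ]

    frag_df, angle_samples = _fragment_table(scene, config)
    tables["fragments"] = frag_df
    for comp in ("assembly", "nucleoid"):
        if comp in angle_samples:
            dist = angle_samples[comp]
            summary += [
                (f"angle_peak_{comp}_deg", dist.peak(config.peak_method)),
                (f"angle_spread_{comp}", dist.circular_spread),
                (f"n_fragments_{comp}", dist.n),
            ]
        else:
            summary.append((f"angle_peak_{comp}_deg", ABSENT))

    asm_fils = scene.filaments_in(Compartment.assembly)
    if asm_fils:
        rp = radial_profile(asm_fils, peak_method=config.peak_method)
        summary += [("radial_peak_nm", rp.peak), ("radial_max_nm", rp.max)]
    else:
        summary.append(("radial_peak_nm", ABSENT))

    cond = scene.get_mask(MaskLabel.condensate)
    nuc = scene.get_mask(MaskLabel.nucleoid)
    mem = scene.get_mask(MaskLabel.membrane)

    ribo = scene.get_points("ribosome")
    if ribo is not None and len(ribo) >= 2:
        nn = nearest_neighbor_distances(ribo)
        summary += [("ribosome_nn_mean_nm", nn.mean), ("n_ribosomes", nn.n)]
        if cond is not None and cond.n_foreground:
            rep = exclusion_report(ribo, cond, config.contact_threshold)
            summary += [
                ("ribosomes_inside_condensate", rep.n_inside),
                ("ribosome_fraction_at_zero", rep.distances.fraction_at_zero),
                ("ribosome_fraction_within_threshold", rep.fraction_within_threshold),
                ("ribosome_condensate_peak_nm", rep.distances.peak(config.peak_method)),
            ]
            df = pd.DataFrame({"distance_nm": rep.distances.values})
            if scene.meta.lamella_z is not None and config.contact_threshold > 0:
                z0, z1 = scene.meta.lamella_z
                z = ribo.coords[:, 2]
                df["near_slab_face"] = (
                    (z - z0 <= config.contact_threshold)
                    | (z1 - z <= config.contact_threshold)
                )
            tables["ribosome_to_condensate"] = df
    else:
        summary.append(("ribosome_nn_mean_nm", ABSENT))

    if cond is not None and cond.n_foreground and nuc is not None and nuc.n_foreground:
        dd = mask_to_mask_distances(cond, nuc)
        summary += [
            ("condensate_nucleoid_min_nm", dd.min),
            ("condensate_nucleoid_mean_nm", dd.mean),
            ("condensate_nucleoid_max_nm", dd.max),
        ]
        tables["condensate_to_nucleoid"] = pd.DataFrame({"distance_nm": dd.values})
    else:
        summary.append(("condensate_nucleoid_mean_nm", ABSENT))

    if cond is not None and cond.n_foreground and mem is not None and mem.n_foreground:
        dm = mask_to_membrane_distance(cond, mem)
        summary += [
            ("condensate_membrane_min_nm", dm.min),
            ("condensate_membrane_mean_nm", dm.mean),
        ]
    else:
        summary.append(("condensate_membrane_mean_nm", ABSENT))

    shape_entity = cond if (cond is not None and cond.n_foreground) else (asm_fils or None)
    if shape_entity is not None:
        sm = principal_shape(shape_entity)
        L, M, S = sm.extents
        summary += [
            ("shape_L_nm", L), ("shape_M_nm", M), ("shape_S_nm", S),
            ("elongation", sm.elongation), ("shape_source", sm.source),
        ]
    else:
        summary.append(("shape_L_nm", ABSENT))

    if nuc is not None and nuc.n_foreground:
        summary.append(("nucleoid_width_nm", nucleoid_width(nuc)))

    tables["summary"] = pd.DataFrame(summary, columns=["key", "value"])
    return tables


def _get(summary_df: pd.DataFrame, key: str, default=np.nan):
    hit = summary_df.loc[summary_df["key"] == key, "value"]
    if hit.empty or (isinstance(hit.iloc[0], str) and hit.iloc[0] == ABSENT):
        return default
    v = hit.iloc[0]
    try:
        return float(v)
    except (TypeError, ValueError):
        return v


def build_genotype_report(scenes, config: RunConfig | None = None,
                          analyzed: list | None = None) -> dict:
    """Pool per-scene analyses by genotype and compare the genotypes.

    ``scenes`` may be Scene objects (analyzed here) or, via ``analyzed``,
    pre-computed ``analyze_scene`` outputs with matching order.  Returns
    tables: per_scene, per_genotype, angle_comparisons, anova.
    """
    config = config or RunConfig()
    if analyzed is None:
        analyzed = [analyze_scene(s, config) for s in scenes]

    rows = []
    pooled_angles: dict[str, list] = {}
    elong: dict[str, list] = {}
    for i, tabs in enumerate(analyzed):
        summ = tabs["summary"]
        geno = str(_get(summ, "genotype", default="?"))
        frag = tabs["fragments"]
        asm_angles = frag.loc[frag["compartment"] == "assembly", "theta_deg"].to_numpy()
        if len(asm_angles):
            pooled_angles.setdefault(geno, []).append(asm_angles)
        e = _get(summ, "elongation")
        if np.isfinite(e):
            elong.setdefault(geno, []).append(e)
        rows.append({
            "scene": i,
            "genotype": geno,
            "n_fragments_assembly": len(asm_angles),
            "angle_peak_deg": _get(summ, "angle_peak_assembly_deg"),
            "angle_spread": _get(summ, "angle_spread_assembly"),
            "radial_peak_nm": _get(summ, "radial_peak_nm"),
            "radial_max_nm": _get(summ, "radial_max_nm"),
            "elongation": e,
            "shape_L_nm": _get(summ, "shape_L_nm"),
            "shape_S_nm": _get(summ, "shape_S_nm"),
            "ribosome_nn_mean_nm": _get(summ, "ribosome_nn_mean_nm"),
            "ribosomes_inside_condensate": _get(summ, "ribosomes_inside_condensate"),
            "condensate_nucleoid_mean_nm": _get(summ, "condensate_nucleoid_mean_nm"),
            "config_hash": config.hash,
        })
    per_scene = pd.DataFrame(rows)

    geno_rows = []
    from .filaments import AngleDistribution

    pooled_dists = {}
    for geno, chunks in sorted(pooled_angles.items()):
        a = np.concatenate(chunks)
        dist = AngleDistribution(a, bin_width=config.bin_width)
        pooled_dists[geno] = dist
        geno_rows.append({
            "genotype": geno,
            "n_scenes": int((per_scene["genotype"] == geno).sum()),
            "n_fragments": dist.n,
            "angle_peak_deg": dist.peak(config.peak_method),
            "angle_spread": dist.circular_spread,
            "peak_method": config.peak_method,
            "fragment_length_nm": config.fragment_length,
            "mean_elongation": float(np.mean(elong.get(geno, [np.nan]))),
            "mean_nucleoid_distance_nm": float(
                per_scene.loc[per_scene["genotype"] == geno,
                              "condensate_nucleoid_mean_nm"].mean()
            ),
            "config_hash": config.hash,
        })
    per_genotype = pd.DataFrame(geno_rows)

    comp_rows = []
    genos = sorted(pooled_dists)
    for i in range(len(genos)):
        for j in range(i + 1, len(genos)):
            ga, gb = genos[i], genos[j]
            results = compare_angle_distributions(
                pooled_dists[ga], pooled_dists[gb], method=None,
                n_permutations=config.n_permutations, rng_seed=config.seed,
                labels=(ga, gb),
            )
            for r in results:
                comp_rows.append({
                    "group_a": ga, "group_b": gb, "test": r.test,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "spread_difference": r.effect["spread_difference"],
                })
    angle_comparisons = pd.DataFrame(
        comp_rows, columns=["group_a", "group_b", "test", "statistic",
                            "p_value", "spread_difference"])

    anova_rows = []
    valid = {g: v for g, v in sorted(elong.items()) if len(v) >= 2}
    if len(valid) >= 2:
        res = compare_scalars_anova(list(valid.values()), labels=list(valid))
        anova_rows.append({
            "metric": "elongation",
            "groups": ",".join(valid),
            "F": res.statistic,
            "p_value": res.p_value,
        })
    anova = pd.DataFrame(anova_rows, columns=["metric", "groups", "F", "p_value"])

    return {
        "per_scene": per_scene,
        "per_genotype": per_genotype,
        "angle_comparisons": angle_comparisons,
        "anova": anova,
    }
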