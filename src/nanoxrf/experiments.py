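"""Seeded validation experiments on synthetic phantoms.

Self-contained, reproducible experiments that exercise the analysis
chain under the study conditions the phantom generator encodes:
uncertainty coverage of the contrast estimator, recovery of known
nucleolar enrichments, granule-detector behaviour under the null and
with inserted granules, fiducial-registration accuracy, calibration
round-trips and count conservation.  The test-suite asserts on these
quantities; the reproduction script reports them.

All experiment sizes (replicate counts, grid sizes) are the defaults
below; they were chosen so each experiment completes in seconds while
leaving Monte-Carlo errors well inside the asserted tolerances.
"""

from __future__ import annotations

import numpy as np

from nanoxrf.contrast import compartment_counts, delta
from nanoxrf.granules import detect_granules
from nanoxrf.maps import ElementMap
from nanoxrf.phantom import (
    Ellipse,
    FullField,
    GranuleSpec,
    PhantomSpec,
    composition_from_reference,
    generate_phantom,
    neuron_phantom_spec,
)
from nanoxrf.quantify import areal_mass, default_standard
from nanoxrf.registration import FiducialSet, SimilarityTransform, estimate_similarity
from nanoxrf.spectra import DetectorModel, Spectrum, _design_matrix, fit_spectrum

__all__ = [
    "contrast_coverage",
    "enrichment_recovery",
    "granule_null",
    "granule_recovery",
    "registration_accuracy",
    "calibration_roundtrip",
    "count_conservation",
    "fitter_roundtrip",
]


def _two_compartment_spec(rates, enrichment, shape=(128, 128), seed=0) -> PhantomSpec:
    r0, c0 = shape[0] / 2.0, shape[1] / 2.0
    nucleolus = {el: r * enrichment.get(el, 1.0) for el, r in rates.items()}
    return PhantomSpec(
        grid_shape=shape,
        pixel_size_nm=50.0,
        geometry=[FullField("nucleus"), Ellipse("nucleolus", (r0, c0), (20.0, 20.0))],
        composition={"nucleus": dict(rates), "nucleolus": nucleolus},
        seed=seed,
    )


def contrast_coverage(n_replicates: int = 200, seed: int = 0, element: str = "Fe") -> dict:
    """Fraction of equal-rate Poisson replicates with |Delta| <= 2 sigma.

    Both compartments share one true rate, so the true contrast is 0 and
    the 2-sigma interval should cover it in ~95.4% of replicates.
    """
    rate = composition_from_reference()["nucleus"][element]
    covered = 0
    for rep in range(n_replicates):
        maps, truth = generate_phantom(
            _two_compartment_spec({element: rate}, {}, shape=(96, 96), seed=seed * 100_003 + rep)
        )
        i = compartment_counts(maps[element], truth.mask("nucleolus"), "nucleolus")
        n = compartment_counts(maps[element], truth.mask("nucleus"), "nucleus")
        r = delta(i, n)
        if abs(r.delta) <= 2 * r.sigma_delta:
            covered += 1
    return {"coverage": covered / n_replicates, "n": n_replicates}


def enrichment_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    enrichment: dict[str, float] | None = None,
) -> dict[str, dict]:
    """Recover known nucleolar enrichments (+66% P, +65% Fe, +47% Zn).

    For each seed a nucleus/nucleolus phantom is generated at reference
    count rates with the stated enrichment factors; the contrast
    estimate must cover the true Delta at 2 sigma in ~95% of seeds.
    """
    enrichment = enrichment or {"P": 1.66, "Fe": 1.65, "Zn": 1.47}
    rates = composition_from_reference()["nucleus"]
    rates = {el: rates[el] for el in enrichment}
    out = {el: {"within_2sigma": 0, "deltas": []} for el in enrichment}
    for rep in range(n_seeds):
        maps, truth = generate_phantom(
            _two_compartment_spec(rates, enrichment, seed=seed * 100_003 + 7919 + rep)
        )
        for el, factor in enrichment.items():
            i = compartment_counts(maps[el], truth.mask("nucleolus"), "nucleolus")
            n = compartment_counts(maps[el], truth.mask("nucleus"), "nucleus")
            r = delta(i, n)
            true_delta = factor - 1.0
            if abs(r.delta - true_delta) <= 2 * r.sigma_delta:
                out[el]["within_2sigma"] += 1
            out[el]["deltas"].append(r.delta)
    return {
        el: {
            "fraction_within_2sigma": rec["within_2sigma"] / n_seeds,
            "mean_delta": float(np.mean(rec["deltas"])),
            "true_delta": enrichment[el] - 1.0,
            "n": n_seeds,
        }
        for el, rec in out.items()
    }


def granule_null(
    n_seeds: int = 50, shape: tuple[int, int] = (100, 100), seed: int = 0
) -> dict:
    """Chance-detection behaviour on a flat Poisson cytoplasm.

    No granules are inserted; everything the detector flags is a false
    positive.  Reports the mean detected component count, the flagged
    area fraction, and the measured per-pixel exceedance probabilities
    (for comparison against the analytic pair-count expectation).
    """
    cyto_rates = composition_from_reference()["cytoplasm"]
    counts, area_frac, p_fe, p_s = [], [], [], []
    for rep in range(n_seeds):
        maps, _ = generate_phantom(
            PhantomSpec(
                grid_shape=shape,
                pixel_size_nm=50.0,
                geometry=[FullField("cytoplasm")],
                composition={"cytoplasm": {"Fe": cyto_rates["Fe"], "S": cyto_rates["S"]}},
                seed=seed * 100_003 + 104_729 + rep,
            )
        )
        cyto = np.ones(shape, bool)
        labels, thr = detect_granules(maps["Fe"], maps["S"], cyto)
        counts.append(int(labels.max()))
        area_frac.append(float((labels > 0).mean()))
        p_fe.append(float((maps["Fe"].counts > thr["Fe"]).mean()))
        p_s.append(float((maps["S"].counts > thr["S"]).mean()))
    return {
        "mean_count": float(np.mean(counts)),
        "mean_area_fraction": float(np.mean(area_frac)),
        "p_exceed_fe": float(np.mean(p_fe)),
        "p_exceed_s": float(np.mean(p_s)),
        "n_pixels": int(np.prod(shape)),
        "n": n_seeds,
    }


def granule_recovery(
    n_seeds: int = 10, n_granules: int = 10, seed: int = 0
) -> dict:
    """Recovery of inserted granules of radius >= 2 px at 5x background.

    A granule counts as recovered when at least one detected label
    overlaps its true footprint.  Also reports the pixel-area agreement
    of matched granules against truth within a one-pixel boundary ring.
    """
    cyto_rates = composition_from_reference()["cytoplasm"]
    found = total = 0
    area_ok = 0
    for rep in range(n_seeds):
        spec = PhantomSpec(
            grid_shape=(128, 128),
            pixel_size_nm=50.0,
            geometry=[FullField("cytoplasm")],
            composition={"cytoplasm": {"Fe": cyto_rates["Fe"], "S": cyto_rates["S"]}},
            granules=GranuleSpec(
                n=n_granules,
                radius_range_nm=(100.0, 200.0),  # 2-4 px at 50 nm
                s_core_rate=4.0 * cyto_rates["S"],
                fe_rate=4.0 * cyto_rates["Fe"],
            ),
            seed=seed * 100_003 + 1_299_709 + rep,
        )
        maps, truth = generate_phantom(spec)
        cyto = np.ones((128, 128), bool)
        labels, _ = detect_granules(maps["Fe"], maps["S"], cyto)
        for g in range(1, truth.granule_labels.max() + 1):
            footprint = truth.granule_labels == g
            total += 1
            hits = np.unique(labels[footprint])
            hits = hits[hits > 0]
            if hits.size:
                found += 1
                detected = np.isin(labels, hits)
                n_true = footprint.sum()
                # perimeter-pixel tolerance on the matched area
                perimeter = 2 * np.pi * np.sqrt(n_true / np.pi) + 4
                if abs(detected.sum() - n_true) <= perimeter + 4:
                    area_ok += 1
    return {
        "recovery": found / total,
        "area_within_tolerance": area_ok / total,
        "n_granules": total,
    }


def registration_accuracy(seed: int = 0, jitter_px: float = 0.5, n_pairs: int = 6) -> dict:
    """Similarity-transform recovery on noiseless and jittered fiducials."""
    rng = np.random.default_rng(seed)
    src = rng.uniform(0, 200, size=(n_pairs, 2))
    true = SimilarityTransform(scale=1.08, rotation=0.22, translation=(14.0, -6.0))
    exact = estimate_similarity(FiducialSet(src, true.apply(src)))
    jittered = estimate_similarity(
        FiducialSet(src, true.apply(src) + rng.normal(0, jitter_px, size=(n_pairs, 2)))
    )
    return {
        "exact_rms_px": exact.rms_residual,
        "exact_scale_error": abs(exact.scale - true.scale),
        "exact_rotation_error": abs(exact.rotation - true.rotation),
        "jitter_rms_px": jittered.rms_residual,
    }


def calibration_roundtrip(seed: int = 0) -> dict:
    """Identity of the calibration relation plus a full phantom round-trip.

    (1) The standard measured against itself (equal mounts) returns its
    own certified Fe areal mass exactly.  (2) A neuron phantom built by
    inverting the calibration from reference areal masses is re-analysed;
    the recovered compartment masses must match within
    Poisson-propagated uncertainty.
    """
    std = default_standard()
    std_equal = type(std)(
        am_fe=std.am_fe, eps_fe=std.eps_fe, s_fe=std.s_fe, s_si=std.s_si,
        t_si_cm=std.t_si_std_cm, t_si_std_cm=std.t_si_std_cm, constants=std.constants,
    )
    identity_am, _ = areal_mass(std_equal.s_fe, std_equal.s_si, std_equal, "Fe")

    from nanoxrf.reference import load_reference_table

    spec = neuron_phantom_spec("ctrl", grid_shape=(160, 160), seed=seed, n_granules=0, organelles=False)
    maps, truth = generate_phantom(spec)
    ref = load_reference_table()
    ref = ref[(ref.condition == "CTRL") & (ref.neuron == 1)]
    max_rel_err = 0.0
    max_sigma_dev = 0.0
    for compartment in ("nucleus", "cytoplasm"):
        region = truth.mask(compartment)
        s_si, _ = maps["Si"].region_sum(region)
        for el in ("P", "S", "Ca", "Fe"):
            s_x, sig_x = maps[el].region_sum(region)
            am, _ = areal_mass(s_x, s_si, std, el)
            want = float(
                ref[(ref.compartment == compartment) & (ref.element == el)].am_ng_cm2.iloc[0]
            )
            am_sigma = am * sig_x / s_x  # Poisson-propagated
            max_rel_err = max(max_rel_err, abs(am - want) / want)
            max_sigma_dev = max(max_sigma_dev, abs(am - want) / am_sigma)
    return {
        "identity_am_fe": identity_am,
        "identity_expected": std.am_fe,
        "roundtrip_max_rel_err": max_rel_err,
        "roundtrip_max_sigma_dev": max_sigma_dev,
    }


def count_conservation(seed: int = 0) -> dict:
    """Granule + background counts equal cytoplasm counts exactly."""
    spec = neuron_phantom_spec("asyn", grid_shape=(128, 128), seed=seed)
    maps, truth = generate_phantom(spec)
    cyto = truth.mask("cytoplasm") | (truth.granule_labels > 0)
    labels, _ = detect_granules(maps["Fe"], maps["S"], cyto)
    residual = 0.0
    for el in ("Fe", "S"):
        counts = maps[el].counts
        residual = max(
            residual,
            abs(counts[labels > 0].sum() + counts[cyto & (labels == 0)].sum() - counts[cyto].sum()),
        )
    return {"max_residual_counts": float(residual)}


def fitter_roundtrip(seed: int = 0) -> dict:
    """Spectral fitter recovery of known K-line areas.

    Single-element (Fe, area 5e4) and overlapping P/S/Ca (1e4 each)
    synthetic spectra; reports recovered/true ratios and the deviation
    in units of the fit sigma.
    """
    detector = DetectorModel()
    rng = np.random.default_rng(seed)
    energies = 0.012 * np.arange(1024)

    prof_fe = _design_matrix(energies, ["Fe"], detector, 0.012)
    counts = rng.poisson(prof_fe[:, 0] * 5e4 + 10.0)
    fit_fe = fit_spectrum(Spectrum(counts, 0.0, 0.012), ["Fe"], detector)

    prof3 = _design_matrix(energies, ["P", "S", "Ca"], detector, 0.012)
    counts3 = rng.poisson(prof3 @ (1e4 * np.ones(3)) + 5.0)
    fit3 = fit_spectrum(Spectrum(counts3, 0.0, 0.012), ["P", "S", "Ca"], detector)

    out = {
        "fe_recovered_ratio": fit_fe.s("Fe") / 5e4,
        "fe_sigma_dev": abs(fit_fe.s("Fe") - 5e4) / fit_fe.sigma_s("Fe"),
    }
    for el in ("P", "S", "Ca"):
        out[f"{el.lower()}_recovered_ratio"] = fit3.s(el) / 1e4
        out[f"{el.lower()}_sigma_dev"] = abs(fit3.s(el) - 1e4) / fit3.sigma_s(el)
    return out
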