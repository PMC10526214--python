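"""Named mixture presets transcribed from the published profile tables.

Each preset carries the printed per-profile sample-size percentages
(as mixture proportions) and per-measure "Mean (SD)" values, plus the
analysed sample size ``n`` and the cluster count ``k`` reported for that
analysis.  Feature keys are cohort score columns.  ``table5b``
additionally carries per-profile demographic composition (hand dominance
and dominant-hand-affected rates) so cluster-specific categorical
structure can be emulated.
"""

from __future__ import annotations

from .synthetic import DemographicRates, ProfileMixtureSpec, mixture_from_table

_PRESET_PARAMS: dict[str, dict] = {
    # Two modalities (TDT, WPST), contralesional hand
    "table3a": {
        "n": 204,
        "k": 3,
        "components": [
            {"proportion": 0.25,
             "means": {"tdt_contra": 77.9, "wpst_contra": 11.5},
             "sds": {"tdt_contra": 8.9, "wpst_contra": 4.1}},
            {"proportion": 0.49,
             "means": {"tdt_contra": 44.1, "wpst_contra": 11.9},
             "sds": {"tdt_contra": 15.0, "wpst_contra": 4.2}},
            {"proportion": 0.26,
             "means": {"tdt_contra": 37.9, "wpst_contra": 26.7},
             "sds": {"tdt_contra": 13.4, "wpst_contra": 6.9}},
        ],
    },
    # Two modalities, ipsilesional hand
    "table3b": {
        "n": 203,
        "k": 3,
        "components": [
            {"proportion": 0.25,
             "means": {"tdt_ipsi": 64.1, "wpst_ipsi": 13.9},
             "sds": {"tdt_ipsi": 12.4, "wpst_ipsi": 4.8}},
            {"proportion": 0.40,
             "means": {"tdt_ipsi": 82.1, "wpst_ipsi": 7.1},
             "sds": {"tdt_ipsi": 7.6, "wpst_ipsi": 2.5}},
            {"proportion": 0.35,
             "means": {"tdt_ipsi": 72.5, "wpst_ipsi": 7.4},
             "sds": {"tdt_ipsi": 11.0, "wpst_ipsi": 2.4}},
        ],
    },
    # Two modalities, both hands
    "table3c": {
        "n": 203,
        "k": 3,
        "components": [
            {"proportion": 0.40,
             "means": {"tdt_contra": 67.8, "wpst_contra": 10.8,
                       "tdt_ipsi": 77.1, "wpst_ipsi": 8.4},
             "sds": {"tdt_contra": 15.1, "wpst_contra": 3.6,
                     "tdt_ipsi": 11.0, "wpst_ipsi": 3.3}},
            {"proportion": 0.26,
             "means": {"tdt_contra": 36.2, "wpst_contra": 12.3,
                       "tdt_ipsi": 64.0, "wpst_ipsi": 9.8},
             "sds": {"tdt_contra": 15.6, "wpst_contra": 5.1,
                     "tdt_ipsi": 10.8, "wpst_ipsi": 5.9}},
            {"proportion": 0.34,
             "means": {"tdt_contra": 41.8, "wpst_contra": 23.8,
                       "tdt_ipsi": 78.7, "wpst_ipsi": 8.9},
             "sds": {"tdt_contra": 14.2, "wpst_contra": 8.1,
                     "tdt_ipsi": 10.7, "wpst_ipsi": 3.8}},
        ],
    },
    # Three modalities, contralesional hand
    "table4a": {
        "n": 144,
        "k": 3,
        "components": [
            {"proportion": 0.28,
             "means": {"tdt_contra": 33.3, "wpst_contra": 24.6, "ftort_contra": 5.5},
             "sds": {"tdt_contra": 15.3, "wpst_contra": 8.7, "ftort_contra": 3.1}},
            {"proportion": 0.47,
             "means": {"tdt_contra": 55.2, "wpst_contra": 10.9, "ftort_contra": 34.4},
             "sds": {"tdt_contra": 16.2, "wpst_contra": 3.3, "ftort_contra": 8.3}},
            {"proportion": 0.25,
             "means": {"tdt_contra": 40.8, "wpst_contra": 18.5, "ftort_contra": 19.9},
             "sds": {"tdt_contra": 15.5, "wpst_contra": 5.9, "ftort_contra": 8.0}},
        ],
    },
    # Three modalities, ipsilesional hand
    "table4b": {
        "n": 141,
        "k": 4,
        "components": [
            {"proportion": 0.23,
             "means": {"tdt_ipsi": 61.9, "wpst_ipsi": 9.6, "ftort_ipsi": 41.0},
             "sds": {"tdt_ipsi": 8.6, "wpst_ipsi": 4.0, "ftort_ipsi": 0.8}},
            {"proportion": 0.21,
             "means": {"tdt_ipsi": 63.1, "wpst_ipsi": 7.6, "ftort_ipsi": 36.9},
             "sds": {"tdt_ipsi": 8.9, "wpst_ipsi": 2.3, "ftort_ipsi": 3.3}},
            {"proportion": 0.27,
             "means": {"tdt_ipsi": 82.2, "wpst_ipsi": 7.2, "ftort_ipsi": 41.6},
             "sds": {"tdt_ipsi": 7.3, "wpst_ipsi": 2.0, "ftort_ipsi": 0.5}},
            {"proportion": 0.29,
             "means": {"tdt_ipsi": 82.3, "wpst_ipsi": 10.8, "ftort_ipsi": 40.1},
             "sds": {"tdt_ipsi": 8.8, "wpst_ipsi": 6.0, "ftort_ipsi": 1.2}},
        ],
    },
    # Three modalities, both hands
    "table5a": {
        "n": 141,
        "k": 4,
        "components": [
            {"proportion": 0.25,
             "means": {"tdt_contra": 65.5, "wpst_contra": 10.8, "ftort_contra": 37.1,
                       "tdt_ipsi": 79.0, "wpst_ipsi": 6.8, "ftort_ipsi": 40.7},
             "sds": {"tdt_contra": 11.7, "wpst_contra": 4.2, "ftort_contra": 5.2,
                     "tdt_ipsi": 8.7, "wpst_ipsi": 2.1, "ftort_ipsi": 1.3}},
            {"proportion": 0.26,
             "means": {"tdt_contra": 30.5, "wpst_contra": 21.4, "ftort_contra": 8.4,
                       "tdt_ipsi": 71.6, "wpst_ipsi": 7.6, "ftort_ipsi": 39.6},
             "sds": {"tdt_contra": 12.2, "wpst_contra": 8.4, "ftort_contra": 5.4,
                     "tdt_ipsi": 12.6, "wpst_ipsi": 2.7, "ftort_ipsi": 2.3}},
            {"proportion": 0.20,
             "means": {"tdt_contra": 52.6, "wpst_contra": 21.3, "ftort_contra": 17.1,
                       "tdt_ipsi": 82.5, "wpst_ipsi": 9.0, "ftort_ipsi": 39.3},
             "sds": {"tdt_contra": 12.0, "wpst_contra": 9.0, "ftort_contra": 11.4,
                     "tdt_ipsi": 11.1, "wpst_ipsi": 3.3, "ftort_ipsi": 4.1}},
            {"proportion": 0.29,
             "means": {"tdt_contra": 36.8, "wpst_contra": 14.2, "ftort_contra": 27.4,
                       "tdt_ipsi": 64.5, "wpst_ipsi": 11.7, "ftort_ipsi": 40.4},
             "sds": {"tdt_contra": 12.9, "wpst_contra": 6.5, "ftort_contra": 12.0,
                     "tdt_ipsi": 11.1, "wpst_ipsi": 5.7, "ftort_ipsi": 1.6}},
        ],
    },
    # Three modalities, both hands, with handedness / dominance covariates
    "table5b": {
        "n": 141,
        "k": 3,
        "components": [
            {"proportion": 0.36,
             "means": {"tdt_contra": 50.9, "wpst_contra": 12.1, "ftort_contra": 36.0,
                       "tdt_ipsi": 73.8, "wpst_ipsi": 8.8, "ftort_ipsi": 40.8},
             "sds": {"tdt_contra": 17.3, "wpst_contra": 4.0, "ftort_contra": 6.9,
                     "tdt_ipsi": 12.1, "wpst_ipsi": 4.3, "ftort_ipsi": 1.4}},
            {"proportion": 0.38,
             "means": {"tdt_contra": 44.7, "wpst_contra": 16.2, "ftort_contra": 18.5,
                       "tdt_ipsi": 75.2, "wpst_ipsi": 7.9, "ftort_ipsi": 40.1},
             "sds": {"tdt_contra": 20.0, "wpst_contra": 7.9, "ftort_contra": 12.8,
                     "tdt_ipsi": 11.9, "wpst_ipsi": 3.2, "ftort_ipsi": 1.9}},
            {"proportion": 0.26,
             "means": {"tdt_contra": 39.0, "wpst_contra": 23.5, "ftort_contra": 10.6,
                       "tdt_ipsi": 71.0, "wpst_ipsi": 10.4, "ftort_ipsi": 39.2},
             "sds": {"tdt_contra": 15.6, "wpst_contra": 9.2, "ftort_contra": 6.5,
                     "tdt_ipsi": 15.2, "wpst_ipsi": 5.1, "ftort_ipsi": 3.8}},
        ],
        # Hand Dominance R/L 46/5, 48/5, 37/0; dominant-affected 32%/100%/8%
        "demographics": {
            "p_right_dominant": 131 / 141,
            "p_unknown_dominance": 0.0,
            "p_dominant_affected": (0.32, 1.0, 0.08),
        },
    },
}

#: Preset name -> {"spec": ProfileMixtureSpec, "n": int, "k": int,
#: "demographics": DemographicRates | None}
MIXTURE_PRESETS: dict[str, dict] = {}
for _name, _p in _PRESET_PARAMS.items():
    MIXTURE_PRESETS[_name] = {
        "spec": mixture_from_table(_p["components"]),
        "n": _p["n"],
        "k": _p["k"],
        "demographics": (
            DemographicRates(**_p["demographics"]) if "demographics" in _p else None
        ),
    }


def get_preset(name: str) -> dict:
    """Return ``{"spec", "n", "k", "demographics"}`` for a named preset."""
    try:
        return MIXTURE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown mixture preset {name!r}; available: {sorted(MIXTURE_PRESETS)}"
        ) from None
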