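"""Bundled demo protocol configs.

Each demo exercises one corner of the supervision vocabulary (window
duration, walker count, metric kind, acceptance rule) on a built-in toy
system, at desk scale.
"""

from __future__ import annotations

DEMOS: dict[str, dict] = {
    # single metric, many short windows — the high-resolution regime
    "double-well-smscore": {
        "system": {"toy": "double_well"},
        "master_seed": 2024,
        "stages": [
            {
                "label": "cross_barrier",
                "metrics": ["suggested"],
                "acceptance": "SMscore",
                "window_ps": 2.0,
                "walkers": 10,
                "terminate": {
                    "kind": "metric_threshold",
                    "slot": 1,
                    "comparator": "<=",
                    "threshold": 2.0,
                },
                "max_batches": 100,
            }
        ],
    },
    # single-walker supervision with tabu restarts
    "double-well-sumd": {
        "system": {"toy": "double_well"},
        "master_seed": 2024,
        "mode": "sumd",
        "stages": [
            {
                "label": "cross_barrier",
                "metrics": ["suggested"],
                "acceptance": "slope",
                "window_ps": 2.0,
                "walkers": 1,
                "terminate": {
                    "kind": "metric_threshold",
                    "slot": 1,
                    "comparator": "<=",
                    "threshold": 2.0,
                },
                "max_batches": 500,
            }
        ],
    },
    # two metrics, DMscore: approach distance + site contacts
    "funnel-binding-dmscore": {
        "system": {"toy": "binding_funnel"},
        "master_seed": 7,
        "stages": [
            {
                "label": "approach",
                "metrics": ["suggested"],
                "acceptance": "SMscore",
                "window_ps": 2.0,
                "walkers": 5,
                "terminate": {
                    "kind": "metric_threshold",
                    "slot": 1,
                    "comparator": "<=",
                    "threshold": 10.0,
                },
                "max_batches": 100,
            },
            {
                "label": "dock",
                "metrics": [
                    "suggested",
                    {
                        "kind": "contact_count",
                        "direction": "increase",
                        "selection_a": "@ligand",
                        "selection_b": "@site",
                        "cutoff": 12.0,
                    },
                ],
                "acceptance": "DMscore",
                "window_ps": 2.0,
                "walkers": 5,
                "terminate": {
                    "kind": "metric_threshold",
                    "slot": 1,
                    "comparator": "<=",
                    "threshold": 2.0,
                },
                "max_batches": 100,
            },
        ],
    },
    # unbinding with the 40 Å stop rule and an unsupervised relaxation stage
    "funnel-unbinding": {
        "system": {"toy": "binding_funnel", "unbinding": True},
        "master_seed": 11,
        "stages": [
            {
                "label": "relax",
                "metrics": ["suggested"],
                "acceptance": "none",
                "window_ps": 2.0,
                "walkers": 1,
                "terminate": {"kind": "max_productive_time", "limit": 4.0},
                "max_batches": 5,
            },
            {
                "label": "escape",
                "metrics": ["suggested"],
                "acceptance": "SMscore",
                "window_ps": 2.0,
                "walkers": 5,
                "terminate": {
                    "kind": "metric_threshold",
                    "slot": 1,
                    "comparator": ">=",
                    "threshold": 40.0,
                },
                "max_batches": 200,
            },
        ],
    },
}
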