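"""Reference data for the globular-domain charge-variant panel.

Published per-variant measurements (melting temperature, relative CSP
sum at 4x molar ratio, apparent 1:1 K_D for the disordered chain) used
as inputs for charge-affinity bookkeeping. Missing K_D (no binding
detected up to 100 uM) is left empty.
"""
from __future__ import annotations

import io

import pandas as pd

NET_CHARGE_CHAIN = -44.0    # disordered polyanion (prothymosin alpha)
NET_CHARGE_DOMAIN = 9.0     # folded globular domain (histone H1.0 GD), wild type

_VARIANT_TABLE = """\
variant	net_charge	tm_K	tm_se_K	rel_csp_sum	rel_csp_sum_se	kd_uM	kd_se_uM
WT	9	321.8	0.1	1.0	0.1	17	6
4R4K	9	318.5	0.1	0.80	0.08	15	8
12K1	11	313.4	0.1	1.7	0.2	2	1
12K1_DE	13	301.6	0.3	2.0	0.2	2.0	0.2
12K2	11	316.5	0.1	1.8	0.2	4.0	0.2
2E2K	13	313.1	0.1	1.8	0.2	1.3	0.2
2E2Q	11	313.3	0.1	1.4	0.1	1.7	0.4
H57K	10	315.6	0.1	1.0	0.1	18	5
H57Q	9	312.2	0.2	1.1	0.1	17	2
8K1	7	323.3	0.1	0.63	0.06	26	6
8K2	7	326.4	0.1	0.34	0.03	191	54
8K3	7	325.9	0.1	0.39	0.04	131	38
6K1	5	327.8	0.1	0.11	0.01
6K2	5	325.7	0.1	0.13	0.01
73_34	9	322.2	0.1	0.54	0.05	36	18
73_66	9	322.1	0.1	0.88	0.08	17	4
73_70	9	324.3	0.1	1.0	0.1	10	2
74_34	9	317.3	0.1	0.63	0.06	64	17
74_67	9	318.9	0.1	0.99	0.09	24	6
74_70	9	322.6	0.1	1.2	0.1	5.7	0.3
82_78	9	321.7	0.1	1.3	0.1	10	4
85_90	9	320.0	0.1	1.0	0.1	10	6
94_90	9	317.3	0.1	1.4	0.1	4.6	0.6
2S1	9	319.2	0.1	0.57	0.05	34	8
2S2	9	321.1	0.1	1.0	0.1	13.8	0.8
2S3	9	326.6	0.1	1.1	0.1	18	3
"""


def variant_panel() -> pd.DataFrame:
    """The charge-variant panel as a DataFrame (K_D in uM; NaN = no binding)."""
    return pd.read_csv(io.StringIO(_VARIANT_TABLE), sep="\t")


def kd_ratio(variant_a: str, variant_b: str) -> float:
    """Ratio of apparent K_D values of two variants (a over b)."""
    panel = variant_panel().set_index("variant")
    return float(panel.loc[variant_a, "kd_uM"] / panel.loc[variant_b, "kd_uM"])
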