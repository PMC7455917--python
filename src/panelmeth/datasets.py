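"""Published summary tables from the 34-sample WBC tumor-suppressor study.

Two small tables, bundled for validation and worked examples:

* :func:`cohort_sequencing_summary` -- per-sample sequencing and coverage
  accounting for the 34 white-blood-cell samples run on the 283-gene
  promoter capture panel (input reads, QC/mapping percentages, reads on
  target, mean coverage of primary and capture regions);
* :func:`differential_region_table` -- the published effect-size table of
  differentially methylated capture regions: minimum and maximum region
  methylation ratio across the cohort, their printed difference and fold
  change, whether the region was called hyper-methylated in a minority of
  individuals, and whether the row sits in the table's upper section
  (> 20 percent-point difference) or lower section (high fold change at
  smaller absolute difference).

Values are the printed (rounded) numbers; recomputing difference and fold
from the rounded min/max can disagree with the printed value in the last
digit.
"""

from __future__ import annotations

import io

import pandas as pd

_COHORT_TSV = """\
sample\tinput_reads\tpct_post_qc\tpct_mapped\tpaired_clipped_reads\tpct_on_primary\tpct_on_capture\tcov_primary\tcov_capture
10046_S2\t5043578\t90.39\t78.71\t3588074\t54.01\t54.31\t209.99\t220.84
10071_S7\t5167738\t89.08\t83.62\t3849392\t44.54\t44.81\t186.40\t196.12
10077_S3\t4622790\t90.13\t81.18\t3382228\t52.35\t52.66\t198.17\t208.34
10078_S8\t4148304\t89.91\t83.59\t3117970\t33.13\t50.13\t175.26\t184.27
10081_S4\t4408742\t89.53\t81.99\t3236368\t50.31\t50.60\t186.37\t195.79
10082_S5\t4146244\t88.90\t82.83\t3053058\t48.82\t49.10\t171.00\t179.62
10086_S6\t4665150\t89.39\t80.91\t3373894\t49.76\t50.06\t186.09\t195.68
10088_S2\t5683572\t88.12\t83.26\t4169990\t49.01\t49.29\t219.04\t230.48
10097_S3\t5372752\t87.46\t84.09\t3951544\t44.74\t45.00\t195.13\t205.17
10107_S1\t4659718\t89.67\t80.24\t3352898\t55.68\t56.00\t213.95\t224.78
10110_S6\t5369964\t86.87\t82.21\t3835038\t47.17\t47.45\t199.76\t210.11
10113_S7\t3862862\t89.44\t83.54\t2886124\t36.11\t36.31\t120.48\t126.52
10117_S5\t4243470\t89.93\t85.80\t3274194\t46.15\t46.42\t169.10\t177.78
10126_S7\t5490894\t87.68\t83.36\t4013294\t44.39\t44.65\t198.79\t209.00
10131_S1\t5338282\t87.00\t82.62\t3836988\t53.58\t53.88\t232.54\t244.35
10146_S6\t4326882\t90.13\t85.57\t3337118\t45.47\t45.73\t168.34\t177.00
10149_S7\t4129130\t90.01\t84.46\t3139126\t45.78\t46.04\t159.55\t167.77
10155_S5\t4450890\t86.31\t84.99\t3264796\t46.65\t46.91\t170.60\t179.37
20011_S4\t5923516\t87.27\t85.49\t4419628\t41.19\t41.42\t203.82\t214.20
20019_S1\t3972578\t89.46\t84.62\t3007020\t49.39\t49.68\t163.80\t172.27
20022_S4\t7091616\t88.48\t81.02\t5083584\t47.19\t47.47\t257.88\t271.25
20023_S1\t7854298\t88.16\t81.78\t5662728\t43.72\t43.98\t269.47\t283.35
20024_S5\t6284900\t88.04\t82.23\t4549698\t41.85\t42.09\t215.05\t225.92
20062_S2\t3554848\t88.54\t84.13\t2648098\t40.36\t40.54\t127.76\t133.78
20068_S3\t3355298\t89.51\t84.38\t2534292\t48.89\t49.18\t138.43\t145.54
20078_S2\t7541786\t88.33\t84.85\t5651984\t38.94\t39.16\t246.67\t259.20
20088_S4\t4083996\t90.28\t84.33\t3109332\t33.27\t33.46\t114.79\t120.70
20092_S3\t4686060\t89.01\t83.38\t3477852\t50.58\t50.88\t196.38\t206.39
20098_S1\t4501632\t88.21\t83.23\t3305210\t53.58\t53.89\t197.69\t207.78
20106_S2\t4430250\t86.96\t83.43\t3214408\t45.12\t45.32\t173.69\t181.84
20117_S4\t4802994\t88.70\t86.01\t3664364\t44.22\t44.48\t178.18\t187.37
20119_S5\t4525080\t89.19\t85.57\t3453670\t46.90\t47.16\t180.35\t189.59
20122_S6\t4741150\t88.79\t85.18\t3585870\t51.76\t52.07\t204.62\t215.16
20160_S3\t5848296\t88.30\t84.30\t4353508\t46.02\t46.28\t220.04\t231.29
"""

_DIFFERENTIAL_TSV = """\
gene\tregion\tmin_ratio\tmax_ratio\tdiff_printed\tfold_printed\thyper\tsection
GAS7\tchr17:10199716-10200316\t0.2670\t0.9332\t0.6662\t3.4951\tFalse\tupper
ELAC2\tchr17:13019069-13019845\t0.4581\t0.8332\t0.3751\t1.8188\tFalse\tupper
GSTM1\tchr1:109686327-109687046\t0.6438\t1.0000\t0.3562\t1.5533\tFalse\tupper
THBS1\tchr15:39579298-39579871\t0.4671\t0.7885\t0.3214\t1.6881\tFalse\tupper
CIITA\tchr16:10874982-10875928\t0.2511\t0.5577\t0.3066\t2.221\tTrue\tupper
RASSF1\tchr3:50339388-50340021\t0.1786\t0.4720\t0.2934\t2.6428\tTrue\tupper
CHN1\tchr2:174846842-174848034\t0.2141\t0.5074\t0.2933\t2.3699\tTrue\tupper
MSH2\tchr2:47401613-47402319\t0.5897\t0.8734\t0.2838\t1.4811\tFalse\tupper
PALB2\tchr16:23642511-23643136\t0.6333\t0.9134\t0.2801\t1.4423\tFalse\tupper
RUNX3\tchr1:24964233-24965550\t0.3920\t0.6479\t0.2559\t1.6528\tFalse\tupper
TP63\tchr3:189789769-189790448\t0.6612\t0.9059\t0.2446\t1.3701\tFalse\tupper
PDCD1LG2\tchr9:5510022-5511326\t0.3182\t0.5511\t0.2330\t1.7319\tTrue\tupper
AIP\tchr11:67481632-67482276\t0.6716\t0.9002\t0.2286\t1.3404\tFalse\tupper
GPC3\tchrX:133986729-133987434\t0.5842\t0.8036\t0.2194\t1.3756\tFalse\tupper
AIP\tchr11:67482202-67482880\t0.1035\t0.3214\t0.2180\t3.1053\tFalse\tupper
GSTP1\tchr11:67581895-67582976\t0.2673\t0.4834\t0.2162\t1.8085\tTrue\tupper
AIP\tchr11:67481257-67481869\t0.7857\t1.0000\t0.2143\t1.2728\tFalse\tupper
XPA\tchr9:97698585-97699193\t0.6991\t0.9130\t0.2139\t1.306\tTrue\tupper
APC\tchr5:112736082-112736959\t0.6361\t0.8479\t0.2118\t1.333\tFalse\tupper
CTCFL\tchr20:57524096-57527440\t0.6554\t0.8663\t0.2109\t1.3218\tFalse\tupper
CASP8\tchr2:201259179-201260169\t0.3698\t0.5799\t0.2102\t1.5681\tFalse\tupper
ZNF668\tchr16:31064314-31065859\t0.4513\t0.6584\t0.2070\t1.4589\tTrue\tupper
RABEP1\tchr17:5281240-5283045\t0.0415\t0.1033\t0.0618\t2.4902\tTrue\tlower
AIP\tchr11:67482382-67483805\t0.0517\t0.1229\t0.0712\t2.3783\tTrue\tlower
RASSF1\tchr3:50338258-50339618\t0.0976\t0.2178\t0.1202\t2.2322\tTrue\tlower
FOXO4\tchrX:71094692-71096928\t0.1256\t0.2592\t0.1335\t2.0629\tFalse\tlower
ZRSR2\tchrX:15789350-15791219\t0.0559\t0.1021\t0.0462\t1.8252\tFalse\tlower
RUNX1T1\tchr8:92102449-92105016\t0.0558\t0.1008\t0.0450\t1.8068\tTrue\tlower
RHOH\tchr4:40196452-40197679\t0.1059\t0.1914\t0.0855\t1.8067\tTrue\tlower
"""


def cohort_sequencing_summary() -> pd.DataFrame:
    """Per-sample sequencing summary of the 34-sample reference cohort."""
    return pd.read_csv(io.StringIO(_COHORT_TSV), sep="\t", index_col="sample")


def differential_region_table() -> pd.DataFrame:
    """Published effect-size table of differentially methylated regions."""
    df = pd.read_csv(io.StringIO(_DIFFERENTIAL_TSV), sep="\t")
    df["hyper"] = df["hyper"].astype(bool)
    return df
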