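"""Small bundled datasets.

``carnivore_oligotype_table`` carries the published per-taxon oligotyping
summary from a gut-microbiome survey of two sympatric Namibian carnivores
(cheetah and black-backed jackal): for each of the 22 bacterial taxa
shared by the two host species, the pooled read counts before and after
noise filtering, the per-species read counts after filtering, the number
of oligotypes resolved in each species, the number of shared oligotypes,
and the number of alignment positions needed to resolve them. The two
oligotype-count columns are the standard input for the bootstrap K-S
comparison of oligotype richness between host species.
"""

from __future__ import annotations

import io

import pandas as pd

_CARNIVORE_TSV = """\
taxon	rank	initial_reads	reads_after_filter	reads_cheetah	reads_jackal	ot_cheetah	ot_jackal	shared_ot	positions
Bacteroides	genus	400000	285663	154366	131297	16	17	16	30
Blautia	genus	99000	81059	41554	39505	6	17	6	21
Clostridium	genus	246200	219461	109061	110400	12	12	12	9
Collinsella	genus	75800	73271	36696	36575	5	6	5	5
Dorea	genus	35000	29436	14862	14574	10	12	7	15
Enterococcus	genus	3100	2606	1295	1311	10	10	10	16
[Eubacterium]	genus	6000	5418	2755	2663	11	9	7	13
Lactobacillus	genus	12000	9719	5151	4568	17	19	12	20
Megamonas	genus	1500	1231	633	598	4	10	4	14
Parabacteroides	genus	8600	6539	3363	3176	13	16	12	35
Peptococcus	genus	39000	36792	18237	18555	9	9	9	5
Peptostreptococcus	genus	13200	12508	6233	6275	10	10	10	8
Phascolarctobacterium	genus	74000	64533	31905	32628	10	8	8	17
[Prevotella]	genus	6300	5157	2682	2475	14	15	14	15
Ruminococcus	genus	10700	9255	4700	4485	6	9	6	25
[Ruminococcus]	genus	89400	78556	40974	37582	10	10	10	10
SMB53	genus	3300	2756	1385	1371	11	12	11	14
Slackia	genus	18000	16058	8458	7627	9	10	4	15
Streptococcus	genus	5400	5168	2605	2563	7	11	6	7
Sutterella	genus	31800	29494	14810	14684	8	8	8	9
Enterobacteriaceae	family	31859	31642	24430	24264	7	7	7	4
Fusobacteriaceae	family	581800	497644	263944	233700	15	15	15	16
"""


def carnivore_oligotype_table() -> pd.DataFrame:
    """Published oligotyping summary for the 22 shared carnivore gut taxa."""
    return pd.read_csv(io.StringIO(_CARNIVORE_TSV), sep="\t")


def carnivore_oligotype_counts() -> tuple[list[int], list[int]]:
    """The two per-taxon oligotype-count vectors (cheetah, jackal)."""
    df = carnivore_oligotype_table()
    return df["ot_cheetah"].tolist(), df["ot_jackal"].tolist()
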