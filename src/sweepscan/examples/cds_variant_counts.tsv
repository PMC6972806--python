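cultivar	snp	indel	sv	affected_genes
R01	18343	3255	0	18578
R02	19226	3498	1772	19606
R15	20616	3674	3864	21045
R16	20709	3717	3243	21092
R17	20739	3729	3839	21150
R18	20754	3892	1539	21044
R19	20713	3859	1580	20957
R08	20631	3779	1723	20932
R09	20966	3950	1645	21222
R10	20741	3821	1734	21014
R11	20710	3818	1761	21005
R13	20578	3733	1733	20870
R14	20790	3894	1835	21063
R03	20842	3968	1719	21107
R04	20514	3759	1792	20819
R05	20556	3790	1768	20856
R06	20682	3844	1814	20980
R07	20625	3806	1681	20897
R12	19399	3479	1617	19739
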