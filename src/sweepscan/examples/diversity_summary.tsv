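sample	sites	polymorphic	invariant	het_obs	pi	f_is
R01	3757493	766270	2991223	0.203931	0.101966	-1
R02	3744896	990688	2754208	0.264544	0.132272	-1
R03	3707982	969817	2738165	0.261548	0.130774	-1
R04	3696447	710257	2986190	0.192146	0.096073	-1
R05	3696432	752846	2943586	0.203668	0.101834	-1
R06	3702222	835330	2866892	0.225629	0.112815	-1
R07	3703072	817899	2885173	0.22087	0.110435	-1
R08	3695026	772295	2922731	0.209009	0.104505	-1
R09	3724660	999430	2725230	0.268328	0.134164	-1
R10	3689825	815105	2874720	0.220906	0.110453	-1
R11	3696730	810340	2886390	0.219205	0.109602	-1
R12	3717058	779507	2937551	0.209711	0.104855	-1
R13	3684153	719034	2965119	0.195169	0.097585	-1
R14	3709958	916329	2793629	0.246992	0.123496	-1
R15	3580820	717627	2863193	0.200409	0.100204	-1
R16	3581599	735908	2845691	0.205469	0.102735	-1
R17	3625457	833616	2791841	0.229934	0.114967	-1
R18	3688694	840950	2847744	0.22798	0.11399	-1
R19	3678202	818311	2859891	0.222476	0.111238	-1
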