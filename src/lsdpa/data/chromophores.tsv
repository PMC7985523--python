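# Chromophore absorption table for lsdpa.
# Compiled and PCHIP-smoothed from the standard literature compilations of
# tissue optical properties (Hb/HbO2 molar extinction compilations at a
# whole-blood reference hemoglobin concentration of 150 g/L, MW 64500 g/mol;
# pure-water absorption; melanosome power law 519*(lambda/500 nm)^-3.48).
# The curve is smoothed so the Hb/HbO2 isosbestic crossing sits at ~800 nm.
# Columns: wavelength_nm  mu_a_hbo2  mu_a_hb  mu_a_water  mu_a_melanin (cm^-1)
wavelength_nm	mu_a_hbo2	mu_a_hb	mu_a_water	mu_a_melanin
660	1.713552	17.280098	0.004100	197.501354
662	1.681219	16.797950	0.004186	195.432672
664	1.650823	16.325228	0.004272	193.391800
666	1.622672	15.862252	0.004360	191.378284
668	1.597071	15.409337	0.004448	189.391674
670	1.574326	14.966803	0.004538	187.431534
672	1.552447	14.532291	0.004628	185.497432
674	1.530720	14.105060	0.004720	183.588948
676	1.511365	13.687852	0.004812	181.705667
678	1.496601	13.283410	0.004906	179.847182
680	1.488648	12.894477	0.005000	178.013097
682	1.485097	12.520802	0.005090	176.203021
684	1.482137	12.159516	0.005173	174.416569
686	1.479880	11.809428	0.005253	172.653366
688	1.478443	11.469348	0.005332	170.913044
690	1.477938	11.138086	0.005415	169.195239
692	1.482913	10.807232	0.005504	167.499596
694	1.495860	10.476963	0.005604	165.825767
696	1.513817	10.158973	0.005718	164.173410
698	1.533820	9.864954	0.005849	162.542188
700	1.552906	9.606599	0.006000	160.931772
702	1.571595	9.382957	0.006192	159.341838
704	1.592089	9.181066	0.006443	157.772068
706	1.613948	8.994610	0.006750	156.222151
708	1.636733	8.817269	0.007113	154.691780
710	1.660003	8.642726	0.007530	153.180654
712	1.682803	8.465485	0.008001	151.688478
714	1.705502	8.289172	0.008525	150.214963
716	1.729654	8.121157	0.009100	148.759824
718	1.756809	7.968809	0.009725	147.322781
720	1.788520	7.839499	0.010400	145.903559
722	1.828446	7.727541	0.011283	144.501889
724	1.877386	7.624034	0.012475	143.117507
726	1.932603	7.531526	0.013886	141.750152
728	1.991356	7.452563	0.015424	140.399568
730	2.050907	7.389692	0.017000	139.065506
732	2.112730	7.335098	0.018912	137.747717
734	2.179024	7.282972	0.021242	136.445961
736	2.248142	7.238865	0.023577	135.159999
738	2.318438	7.208329	0.025501	133.889597
740	2.388263	7.196917	0.026600	132.634526
742	2.457248	7.209721	0.027117	131.394559
744	2.526508	7.244755	0.027558	130.169476
746	2.596618	7.296947	0.027900	128.959058
748	2.668151	7.361229	0.028121	127.763092
750	2.741683	7.432530	0.028200	126.581366
752	2.818955	7.567371	0.027993	125.413673
754	2.899682	7.768963	0.027475	124.259811
756	2.981399	7.952274	0.026800	123.119580
758	3.061641	8.032274	0.026124	121.992783
760	3.137942	7.998806	0.025600	120.879226
762	3.210016	7.925177	0.025211	119.778721
764	3.279663	7.784776	0.024845	118.691081
766	3.347544	7.559700	0.024513	117.616122
768	3.414320	7.303169	0.024228	116.553663
770	3.480652	7.068401	0.024000	115.503528
772	3.546971	6.865563	0.023828	114.465542
774	3.612864	6.667638	0.023689	113.439533
776	3.677726	6.472066	0.023566	112.425333
778	3.740954	6.276291	0.023442	111.422776
780	3.801943	6.077754	0.023300	110.431699
782	3.860011	5.873215	0.023120	109.451942
784	3.915683	5.664367	0.022913	108.483347
786	3.970167	5.456045	0.022706	107.525758
788	4.024669	5.253088	0.022526	106.579023
790	4.080395	5.060332	0.022400	105.642993
792	4.137978	4.860077	0.022311	104.717518
794	4.196622	4.648548	0.022230	103.802455
796	4.255390	4.451468	0.022162	102.897660
798	4.313347	4.294563	0.022117	102.002992
800	4.369557	4.203557	0.022100	101.118314
802	4.423497	4.160553	0.022200	100.243488
804	4.475842	4.128141	0.022483	99.378382
806	4.527456	4.102772	0.022918	98.522864
808	4.579203	4.080900	0.023480	97.676803
810	4.631944	4.058976	0.024138	96.840073
812	4.685716	4.037532	0.024866	96.012547
814	4.739950	4.018547	0.025634	95.194103
816	4.794608	4.000647	0.026414	94.384618
818	4.849651	3.982453	0.027179	93.583972
820	4.905042	3.962588	0.027900	92.792049
822	4.961868	3.938703	0.028613	92.008732
824	5.020731	3.910445	0.029370	91.233908
826	5.080861	3.879437	0.030165	90.467462
828	5.141490	3.847300	0.030995	89.709286
830	5.201849	3.815656	0.031853	88.959270
832	5.261167	3.786129	0.032735	88.217307
834	5.318676	3.760340	0.033635	87.483292
836	5.373607	3.739910	0.034550	86.757120
838	5.425190	3.726463	0.035473	86.038690
840	5.472656	3.721620	0.036400	85.327900
842	5.516555	3.721968	0.037350	84.624652
844	5.558165	3.722977	0.038338	83.928847
846	5.597810	3.724592	0.039357	83.240391
848	5.635813	3.726761	0.040397	82.559187
850	5.672499	3.729429	0.041450	81.885143
852	5.708191	3.732544	0.042507	81.218167
854	5.743213	3.736051	0.043559	80.558168
856	5.777889	3.739898	0.044598	79.905058
858	5.812541	3.744030	0.045614	79.258749
860	5.847495	3.748394	0.046600	78.619153
862	5.882832	3.754552	0.047547	77.986187
864	5.918275	3.763745	0.048461	77.359766
866	5.953605	3.775436	0.049351	76.739808
868	5.988605	3.789091	0.050228	76.126231
870	6.023058	3.804174	0.051103	75.518955
872	6.056746	3.820149	0.051985	74.917902
874	6.089451	3.836482	0.052886	74.322992
876	6.120956	3.852635	0.053815	73.734151
878	6.151043	3.868075	0.054783	73.151302
880	6.179496	3.882266	0.055800	72.574370
882	6.206570	3.895375	0.056819	72.003283
884	6.232706	3.908051	0.057805	71.437968
886	6.257964	3.920481	0.058786	70.878354
888	6.282402	3.932848	0.059790	70.324370
890	6.306080	3.945340	0.060846	69.775949
892	6.329055	3.958140	0.061983	69.233021
894	6.351386	3.971434	0.063228	68.695519
896	6.373133	3.985408	0.064611	68.163377
898	6.394355	4.000247	0.066158	67.636530
900	6.415109	4.016137	0.067900	67.114914
902	6.435489	4.033997	0.069926	66.598465
904	6.455514	4.054230	0.072320	66.087121
906	6.475137	4.076243	0.075101	65.580820
908	6.494310	4.099442	0.078289	65.079502
910	6.512983	4.123234	0.081901	64.583106
912	6.531109	4.147026	0.085957	64.091574
914	6.548640	4.170225	0.090476	63.604847
916	6.565526	4.192237	0.095477	63.122868
918	6.581720	4.212470	0.100979	62.645581
920	6.597174	4.230331	0.107000	62.172930
922	6.612647	4.247425	0.115176	61.704859
924	6.628651	4.265343	0.126725	61.241316
926	6.644769	4.283467	0.141035	60.782245
928	6.660584	4.301180	0.157500	60.327595
930	6.675677	4.317862	0.175509	59.877314
932	6.689630	4.332897	0.194453	59.431350
934	6.702026	4.345666	0.213723	58.989653
936	6.712446	4.355552	0.232711	58.552173
938	6.720474	4.361936	0.250806	58.118861
940	6.725690	4.364202	0.267400	57.689668
942	6.729264	4.364175	0.283003	57.264547
944	6.732618	4.363988	0.298532	56.843451
946	6.735715	4.363479	0.313985	56.426332
948	6.738518	4.362488	0.329362	56.013145
950	6.740990	4.360855	0.344663	55.603845
952	6.743095	4.358419	0.359887	55.198388
954	6.744797	4.355018	0.375033	54.796728
956	6.746057	4.350494	0.390101	54.398824
958	6.746841	4.344684	0.405090	54.004631
960	6.747110	4.337428	0.420000	53.614108
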