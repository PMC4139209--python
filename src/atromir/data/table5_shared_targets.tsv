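# Transcribed shared-target table: genes anti-correlated with both miR-206 and miR-21
# in denervated mouse muscle; per miRNA: number of predicted seed sites and ddG score
# (dimensionless energy units; more negative = stronger predicted repression).
gene_symbol	sites_206	score_206	sites_21	score_21
Acot12	3	-5.49	1	-1.46
Acpp	3	-2.95	1	-1.13
Adam7	1	-9.72	1	-2.8
Adarb2	2	-1.83	2	-4.22
Adipor1	2	-3.94	1	-1.18
Aff4	5	-2.55	1	-1.77
Alg2	1	-6.22	2	-0.52
Ap3m1	3	-0.46	2	-1.93
Atp11a	2	-0.46	1	-1.01
Atp7a	2	-6.75	3	-2.33
Car8	2	-4.38	3	-2.71
Cav1	2	-0.36	2	-1.07
Cav2	4	-2.97	2	-9.2
Ccdc50	3	-7.13	2	-3.51
Ccl9	2	-9.12	1	-4.47
Ccng1	1	-0.4	2	-1.28
Cd2ap	4	-7.98	3	-1.25
Chst11	3	-2.96	1	-0.59
Cited2	2	-7.01	1	-1.78
Clec5a	3	-9.81	3	-4.61
Cmah	1	-2.45	5	-0.68
Col4a1	2	-1.46	1	-1.23
Commd8	2	-8.52	2	-4.71
Copg2	1	-3.29	1	-2.23
Cpd	2	-8.7	4	-1.54
Ddx19b	4	-10.62	3	-6.29
Dkk2	4	-9.29	5	-1.35
Dlg3	4	-2.11	1	-2.21
Dnajb4	1	-8.33	2	-10.58
Dph2	1	-9.24	1	-0.99
Dusp11	3	-11.48	2	-1.42
Ecm2	1	-1.31	2	-1.52
Ehf	1	-2.23	2	-0.096
Eif4e3	1	-3.01	1	-10.9
Esrrg	2	-15.54	3	-5.01
Fgl2	3	-9.23	3	-2.32
Fnbp1	1	-1.68	1	-2.19
Foxo1	3	-4.72	1	-0.28
Fzd7	1	-2.76	3	-0.59
Gabpa	3	-2.58	1	-3.99
Gda	3	-5.35	2	-0.75
Gja1	2	-3.96	1	-1.9
Glis2	2	-8.7	2	-7.31
Gnpnat1	2	-9.86	1	-0.16
Grk1	1	-6.32	8	-4.61
Grpel2	2	-2.88	2	-1.43
Gulp1	1	-3.93	2	-0.1
Hnrnpu	1	-0.86	1	-3.11
Hnrpll	1	-1.17	1	-3.13
Homer1	2	-13.28	2	-0.39
Hs2st1	3	-1.7	2	-0.16
Hs3st3b1	3	-6.53	2	-1.4
Il21	1	-0.19	4	-7.34
Impact	3	-2.14	2	-2.74
Itsn1	7	-3.63	3	-1.09
Map3k7ip3	3	-0.37	3	-3.07
Mbd2	2	-3.14	1	-1.08
Mbnl1	1	-5.8	2	-3.16
Mcfd2	1	-4.5	2	-1.08
Mdfic	3	-4.13	2	-3.8
Mtfr1	1	-3.15	3	-1.49
Myo10	2	-6.75	2	-5.72
Myo5a	3	-4.03	3	-2.32
Ncl	3	-4.45	2	-2.89
Nfib	4	-4.19	5	-6.72
Nras	4	-1.12	3	-0.85
Nrk	2	-0.61	1	-0.76
Ntrk2	5	-5.22	1	-1.54
Oasl2	2	-7.24	1	-4.65
Orc41	3	-1.64	2	-4.97
Pard3	2	-4.04	1	-3.91
Pbx1	1	-9.33	2	-2.96
Pcbp1	1	-3.41	1	-4.93
Pcdh10	2	-2.35	2	-2.12
Pclo	1	-2	2	-1.23
Pdcd10	2	-3.79	1	-2.23
Pdzd2	6	-5.14	3	-2.29
Peli2	5	-8.43	3	-0.57
Pfn2	2	-1.92	2	-0.75
Pitpna	4	-6.9	3	-3.7
Pja2	1	-1.79	2	-1
Plagl1	1	-7.8	3	-0.36
Pls3	2	-7.03	1	-1.84
Ptgs1	1	-2.56	1	-5.16
Pwp1	2	-4.89	1	-1.26
Rab6	1	-1.39	3	-2.68
Rabgap1l	6	-10.08	5	-6.03
Rad51l3	1	-3.95	2	-3.24
Rag2	1	-3.04	2	-0.18
Rbm25	2	-1.25	2	-0.48
Rbpms	3	-0.48	1	-1.3
Rps6kb1	3	-2.9	1	-0.048
Sfrs3	1	-0.65	3	-3.84
Slc1a4	2	-3.31	2	-5.47
Slc25a23	4	-10.07	1	-2.74
Slc25a36	3	-3.11	3	-3.9
Slc35a5	2	-4.24	4	-7.15
Slc4a4	1	-1.73	2	-2.07
Slc7a11	8	-8.43	5	-8.22
Socs5	1	-0.53	2	-2.79
Sox6	7	-8.18	6	-7.92
Srpk2	5	-6.22	3	-0.84
St6gal1	3	-1.78	1	-2.66
Stard5	2	-1.52	2	-1.25
Steap2	7	-9.43	4	-1.91
Stx17	4	-4.52	1	-0.93
Suz12	1	-0.34	2	-4.74
Tbc1d15	1	-9.61	3	-0.75
Tcam1	2	-6.13	1	-1.61
Tm9sf3	2	-1.95	3	-0.98
Tmem100	2	-5.17	2	-0.63
Tmem167	4	-0.95	2	-2.35
Tmod2	8	-8.69	1	-0.28
Trp63	3	-2.25	3	-0.71
Tsc22d2	6	-9.1	3	-4.67
Ubc	1	-14.07	1	-3.42
Ube2g1	2	-12.82	2	-1.86
Usp33	1	-16.97	3	-2.38
Vps37a	9	-7.57	2	-4.96
Wbp2	1	-3.74	1	-6.61
Wtap	1	-4.21	1	-7.76
Yap1	1	-5.83	3	-0.47
Yy1	1	-5.33	2	-8.2
Zbtb33	1	-1.53	4	-2.71
Zcchc8	2	-7.1	2	-1.73
Zfp111	5	-11.5	2	-3.81
Zfp238	1	-4.86	2	-4.54
Zfp36l1	2	-4.72	2	-2.57
Zfp654	4	-5.14	2	-2.76
Zfp704	8	-2.99	6	-3.59
Zfp93	1	-3.34	1	-1.22
Zrsr2	1	-3.49	3	-1.32
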