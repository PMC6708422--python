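label	1A-216.5:217.2	1B-195.4:227.2	1B-355.4:368.3	3B-056.5:056.6	3B-239.1:250.3	3B-259.1:293.4	5A-216.7:216.8	5D-503.5:513.6	6A-032.4:032.4	6A-103.7:105.9	6A-188.9:205.5	6B-388.3:398.0	7A-371.3:399.2	Ppd-D1	Rht-B1	Vrn-B1	Psy-A1
1A-216.5:217.2	1.00	0.34	0.22	0.20	0.25	0.38	0.27	0.26	0.28	0.35	0.36	0.45	0.39	0.39	0.32	0.17	0.20
1B-195.4:227.2	0.34	1.00	0.51	0.32	0.46	0.46	0.43	0.33	0.28	0.28	0.41	0.31	0.43	0.23	0.25	0.23	0.44
1B-355.4:368.3	0.22	0.51	1.00	0.42	0.49	0.49	0.42	0.28	0.22	0.35	0.53	0.36	0.54	0.31	0.39	0.23	0.38
3B-056.5:056.6	0.20	0.32	0.42	1.00	0.34	0.37	0.42	0.23	NA	0.22	0.42	0.25	0.40	0.15	0.31	0.15	0.32
3B-239.1:250.3	0.25	0.50	0.49	0.34	1.00	0.75	0.40	0.31	0.37	0.37	0.52	0.29	0.53	0.26	0.39	0.22	0.32
3B-259.1:293.4	0.38	0.53	0.49	0.37	0.75	1.00	0.40	0.44	0.30	0.56	0.47	0.52	0.53	0.46	0.44	0.25	0.30
5A-216.7:216.8	0.27	0.43	0.42	0.42	0.40	0.40	1.00	0.22	0.25	0.39	0.50	0.37	0.47	0.35	0.57	0.17	0.36
5D-503.5:513.6	0.26	0.33	0.28	0.23	0.31	0.44	0.22	1.00	0.44	0.39	0.30	0.36	0.42	0.30	0.21	NA	0.16
6A-032.4:032.4	0.28	0.28	0.22	NA	0.37	0.30	0.25	0.44	1.00	0.44	0.26	0.32	0.34	0.26	0.21	NA	0.18
6A-103.7:105.9	0.35	0.28	0.35	0.22	0.37	0.56	0.39	0.39	0.44	1.00	0.40	0.55	0.50	0.50	0.40	0.17	0.25
6A-188.9:205.5	0.36	0.41	0.53	0.42	0.52	0.47	0.50	0.30	0.26	0.40	1.00	0.43	0.40	0.25	0.37	0.19	0.22
6B-388.3:398.0	0.45	0.31	0.36	0.25	0.29	0.52	0.37	0.36	0.32	0.55	0.43	1.00	0.58	0.54	0.39	NA	0.25
7A-371.3:399.2	0.39	0.47	0.54	0.40	0.53	0.53	0.47	0.42	0.34	0.50	0.40	0.58	1.00	0.45	0.41	0.21	0.26
Ppd-D1	0.39	0.27	0.31	0.15	0.26	0.46	0.35	0.30	0.26	0.50	0.25	0.54	0.45	1.00	0.44	0.15	0.24
Rht-B1	0.32	0.25	0.39	0.31	0.39	0.44	0.57	0.21	0.21	0.40	0.37	0.39	0.41	0.44	1.00	0.20	0.44
Vrn-B1	0.17	0.23	0.23	0.15	0.22	0.25	0.17	NA	NA	0.17	0.19	NA	0.21	0.15	0.20	1.00	0.18
Psy-A1	0.20	0.44	0.38	0.32	0.32	0.30	0.36	0.16	0.18	0.25	0.22	0.25	0.26	0.24	0.44	0.18	1.00
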