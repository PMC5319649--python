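accession	sample	lid_unique	lid_floral	pitcher_unique	pitcher_floral
Darlingtonia californica 18	18	5	0	16	0
Sarracenia alata 14	14	4	1	3	1
Sarracenia alata 46	46	14	2	1	1
Sarracenia alata 28	28	3	1	2	0
Sarracenia alata 40	40	5	1	3	0
Sarracenia alata 42	42	2	0	11	0
Sarracenia flava 20	20	4	0	13	1
Sarracenia flava var. ornata 29	29	12	3	4	1
Sarracenia flava var. atropurpurea 31	31	4	0	25	6
Sarracenia flava var. atropurpurea 35	35	18	1	11	1
Sarracenia flava var. atropurpurea 1	1	10	2	11	2
Sarracenia flava var. cuprea 10	10	2	1	5	0
Sarracenia flava var. flava 11	11	9	1	12	1
Sarracenia flava var. heterophylla 21	21	5	2	4	1
Sarracenia flava var. maxima 44	44	1	0	8	1
Sarracenia flava var. rubricorpora 8	8	2	1	3	0
Sarracenia flava var. rugelii 32	32	3	0	4	0
Sarracenia leucophylla 33	33	5	0	11	0
Sarracenia leucophylla 17	17	15	4	5	1
Sarracenia leucophylla 12	12	14	3	0	0
Sarracenia leucophylla 'Schnell's Ghost' 45	45	16	3	1	0
Sarracenia leucophylla var. alba 26	26	10	0	19	3
Sarracenia minor 15	15	7	0	1	0
Sarracenia minor 4	4	5	2	9	0
Sarracenia minor var. okefenokeensis 5	5	15	3	16	6
Sarracenia oreophila 22	22	7	2	7	0
Sarracenia oreophila 27	27	6	0	3	0
Sarracenia psittacina f. heterophylla 6	6	1	1	0	0
Sarracenia psittacina f. heterophylla 24	24	3	1	1	0
Sarracenia psittacina 13	13	10	3	9	5
Sarracenia psittacina 43	43	3	0	5	0
Sarracenia purpurea subsp. purpurea 16	16	1	0	0	0
Sarracenia purpurea subsp. purpurea 19	19	1	0	8	4
Sarracenia purpurea subsp. purpurea f. heterophylla 38	38	4	1	5	2
Sarracenia purpurea subsp. venosa 36	36	15	2	17	1
Sarracenia purpurea subsp. venosa 47	47	3	0	2	0
Sarracenia purpurea subsp. venosa 30	30	2	0	1	0
Sarracenia purpurea subsp. venosa 37	37	4	2	9	0
Sarracenia purpurea subsp. venosa var. burkei 34	34	3	1	3	0
Sarracenia purpurea subsp. venosa var. burkei 7	7	5	0	5	0
Sarracenia purpurea subsp. venosa var. burkei 39	39	0	0	10	5
Sarracenia purpurea subsp. venosa var. burkei f. luteola 48	48	4	0	2	0
Sarracenia purpurea subsp. venosa var. montana 41	41	11	1	0	0
Sarracenia purpurea subsp. venosa var. montana 9	9	13	0	2	1
Sarracenia rubra subsp. alabamensis 2	2	2	0	7	1
Sarracenia rubra subsp. gulfensis 25	25	6	0	7	0
Sarracenia rubra subsp. jonesii 3	3	3	0	7	2
Sarracenia rubra subsp. wherryi 23	23	12	3	11	4
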