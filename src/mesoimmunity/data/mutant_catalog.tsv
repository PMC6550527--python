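phage	subcluster	inheritance	lysogen_recovery	parent	mutant_type	mutations	l5_clade
Bxb1	A1	int	Yes	NA	NA	NA	0
Dreamboat	A1	int	Yes	NA	NA	NA	0
Petruchio	A1	int	Yes	NA	NA	NA	0
MissWhite	A2	int	No	?	NA	(Δrep)	1
D29	A2	int	NA	?	NA	(rep Δ5' end)	1
Echild	A2	parABS	No	NA	NA	NA	1
Journey13	A2	int	No	NA	NA	NA	1
Piro94	A2	int	No	NA	NA	NA	1
ArcherNM	A2	parABS	Yes	NA	NA	NA	1
Drake55	A2	int	Yes	NA	NA	NA	1
Jaan	A2	int	Yes	NA	NA	NA	1
L5	A2	int	Yes	NA	NA	NA	1
LadyBird	A2	parABS	Yes	NA	NA	NA	1
Larenn	A2	int	Yes	NA	NA	NA	1
RedRock	A2	parABS	Yes	NA	NA	NA	1
Serenity	A2	int	Yes	NA	NA	NA	1
StarStuff	A2	int	Yes	NA	NA	NA	1
Trixie	A2	int	Yes	NA	NA	NA	1
Updawg	A2	int	Yes	NA	NA	NA	1
Peaches	A4	int	NA	NA	NA	NA	0
Jeffabunny	A6	parABS	No	?	NA	(Δrep)	1
DaVinci	A6	parABS	Yes	NA	NA	NA	1
Gladiator	A6	parABS	Yes	NA	NA	NA	1
Alma	A9	parABS	Yes	NA	NA	NA	1
Pioneer	A9	parABS	Yes	NA	NA	NA	1
Et2Brutus	A11	parABS	Yes	NA	NA	NA	1
Mulciber	A11	parABS	Yes	NA	NA	NA	1
DarthPhader	A12	int	Yes	NA	NA	NA	1
EagleEye	A16	parABS	Yes	NA	NA	NA	1
phiTM45	A1	int	NA	Bxb1	Bxb1 CRS DEM	G44351A (Rep Q138*)	0
phiTM1	A2	int	Yes	L5	BRED	44333:44334 27-bp ins (Rep-HA)	1
phiTM4	A2	int	No	phiTM1	Unintentional isolate	G43843T (gp70 A145E)	1
phiTM6	A2	int	Yes	L5	BRED	44333:44334 24-bp ins (Rep-FLAG)	1
phiTM33	A2	int	No	Che12	Unintentional isolate	Δ44705:47517 (rep Δ5' end); C18749A (gp29 F223L)	1
phiTM41	A2	int	Yes	L5	Trixie Lys DEM	G50942T (gp89 F47L)	1
phiTM42	A2	int	NA	Trixie/RedRock	Trixie Lys DEM	rec Tx 44620:44630 and RR 44127:44137; rec Tx 53508:53524 and RR 53314:53330; RR Δ47296:51394; RR 45315:45316 G insertion (Rep R149fs)	1
phiTM43	A2	int	No	D29	Unintentional isolate	C25024T (gp32 P202S)	1
phiTM44	A2	int	No	D29	Unintentional isolate	C25024A (gp32 P202T); C40378T (gp59.2 sense)	1
phiTM38	A2	int	NA	phiTM44	Et2Brutus Lys DEM	C45518A (rep pm)	1
phiTM46	A6	parABS	NA	DaVinci	Gladiator CRS DEM	43427:43428 G insertion (Rep R52fs)	1
phiTM47	A6	parABS	NA	Gladiator	Gladiator CRS DEM	43878:43879 G insertion (Rep G135fs)	1
phiTM35	A9	parABS	NA	Pioneer	EagleEye Lys DEM	G44573T (Rep Y48*); Δ3425:5091	1
phiTM39	A11	parABS	NA	Et2Brutus	L5 Lys DEM	G44580T (Rep S102*); T7649G (Holin V9G); G50548T (gp98 sense)	1
phiTM40	A11	parABS	NA	Et2Brutus	Trixie Lys DEM	G44772A (Rep A38V); T7667G (Holin I15S)	1
phiTM36	A16	parABS	NA	EagleEye	Pioneer Lys DEM	Δ45310:48001 (Δrep)	1
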