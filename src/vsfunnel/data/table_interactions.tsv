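db	compound	program	chain	residue	cell
MEGx	NP-016468	GOLD	A	F88	HD
MEGx	NP-016468	GOLD	A	A91	HB
MEGx	NP-016468	GOLD	A	T94	HB
MEGx	NP-016468	GOLD	A	F95	HD
MEGx	NP-016468	GOLD	A	M105	HD
MEGx	NP-016468	GOLD	A	F108	HD
MEGx	NP-016468	GOLD	A	K110	HB
MEGx	NP-016468	GOLD	A	F293	HD
MEGx	NP-016468	GOLD	A	I310	HD
MEGx	NP-016468	GOLD	B	W167	HD
MEGx	NP-016468	GOLD	B	Y298	HB
MEGx	NP-016468	GOLD	C	F95	HD
MEGx	NP-016468	DockThor	A	F88	HD
MEGx	NP-016468	DockThor	A	A91	HB
MEGx	NP-016468	DockThor	A	F95	HD
MEGx	NP-016468	DockThor	A	K110	HB
MEGx	NP-016468	DockThor	A	F293	HD
MEGx	NP-016468	DockThor	A	Y295	HD
MEGx	NP-016468	DockThor	A	K297	HB
MEGx	NP-016468	DockThor	A	I310	HD
MEGx	NP-016468	DockThor	B	Y298	HD, HB
MEGx	NP-025047	GOLD	A	F88	HD
MEGx	NP-025047	GOLD	A	T94	HB
MEGx	NP-025047	GOLD	A	F95	HD
MEGx	NP-025047	GOLD	A	M105	HD
MEGx	NP-025047	GOLD	A	Y295	HD
MEGx	NP-025047	GOLD	A	K297	HB
MEGx	NP-025047	GOLD	A	I310	HD
MEGx	NP-025047	GOLD	A	V312	HD
MEGx	NP-025047	GOLD	B	Y295	HD
MEGx	NP-025047	GOLD	B	Y298	HD
MEGx	NP-025047	DockThor	A	F88	HD
MEGx	NP-025047	DockThor	A	F95	HD
MEGx	NP-025047	DockThor	A	P96	HD
MEGx	NP-025047	DockThor	A	F103	HD
MEGx	NP-025047	DockThor	A	M105	HD
MEGx	NP-025047	DockThor	A	F293	HD
MEGx	NP-025047	DockThor	A	K297	π-C, SB
MEGx	NP-025047	DockThor	A	I310	HD
MEGx	NP-025047	DockThor	A	V312	HD
MEGx	NP-025047	DockThor	B	F293	HD
MEGx	NP-025047	DockThor	B	Y295	HD
MEGx	NP-025047	DockThor	B	A296	HB
MEGx	NP-025357	GOLD	A	F88	HD
MEGx	NP-025357	GOLD	A	F95	HD
MEGx	NP-025357	GOLD	A	F103	HD
MEGx	NP-025357	GOLD	A	F293	HD
MEGx	NP-025357	GOLD	A	Y295	HB
MEGx	NP-025357	GOLD	B	W167	HD
MEGx	NP-025357	GOLD	B	Y298	HD, HB
MEGx	NP-025357	DockThor	A	F95	HD
MEGx	NP-025357	DockThor	A	K110	HB
MEGx	NP-025357	DockThor	A	Y295	HB, π-π
MEGx	NP-025357	DockThor	A	K297	HB
MEGx	NP-025357	DockThor	A	I310	HD
MEGx	NP-025357	DockThor	A	V312	HD
MEGx	NP-025358	GOLD	A	F88	HD
MEGx	NP-025358	GOLD	A	F95	HD
MEGx	NP-025358	GOLD	A	F103	HD
MEGx	NP-025358	GOLD	A	K110	HB
MEGx	NP-025358	GOLD	A	F293	HD
MEGx	NP-025358	GOLD	A	Y295	HB, HB
MEGx	NP-025358	GOLD	B	W167	HD
MEGx	NP-025358	GOLD	B	Y298	HD
MEGx	NP-025358	DockThor	A	D92	HD
MEGx	NP-025358	DockThor	A	Y93	HB
MEGx	NP-025358	DockThor	A	F95	HD
MEGx	NP-025358	DockThor	A	K110	HB
MEGx	NP-025358	DockThor	A	Y295	HD, HB, π-π
MEGx	NP-025358	DockThor	A	K297	π-π
MEGx	NP-025358	DockThor	A	I310	HD
MEGx	NP-025358	DockThor	B	Y298	HD
NATx	NAT28-412055	GOLD	A	F88	HD
NATx	NAT28-412055	GOLD	A	F95	HD
NATx	NAT28-412055	GOLD	A	M105	HD
NATx	NAT28-412055	GOLD	A	F293	HD
NATx	NAT28-412055	GOLD	A	Y295	HD
NATx	NAT28-412055	GOLD	A	K297	HBA
NATx	NAT28-412055	GOLD	A	I310	HD
NATx	NAT28-412055	GOLD	A	V312	HD
NATx	NAT28-412055	GOLD	B	Y295	HD
NATx	NAT28-412055	GOLD	B	A296	HD
NATx	NAT28-412055	GOLD	B	Y298	HD
NATx	NAT28-412055	GOLD	C	F95	HD
NATx	NAT28-412055	DockThor	A	F88	HD
NATx	NAT28-412055	DockThor	A	D92	HD
NATx	NAT28-412055	DockThor	A	F95	HD
NATx	NAT28-412055	DockThor	A	F103	HD
NATx	NAT28-412055	DockThor	A	F293	HD
NATx	NAT28-412055	DockThor	A	I310	HD
NATx	NAT28-412055	DockThor	B	F95	HD
NATx	NAT28-412055	DockThor	B	Y293	HD
NATx	NAT28-412055	DockThor	B	Y298	HD
NATx	NAT28-416626	GOLD	A	F88	HD
NATx	NAT28-416626	GOLD	A	F95	HD
NATx	NAT28-416626	GOLD	A	F103	HD
NATx	NAT28-416626	GOLD	A	M105	HD
NATx	NAT28-416626	GOLD	A	F293	HD
NATx	NAT28-416626	GOLD	A	Y295	HD
NATx	NAT28-416626	GOLD	A	K297	HBA
NATx	NAT28-416626	GOLD	A	I310	HD
NATx	NAT28-416626	GOLD	A	V312	HD
NATx	NAT28-416626	GOLD	B	W167	HD
NATx	NAT28-416626	GOLD	B	A296	HD
NATx	NAT28-416626	GOLD	C	Q98	HB
NATx	NAT28-416626	DockThor	A	F95	HD
NATx	NAT28-416626	DockThor	A	F103	HD
NATx	NAT28-416626	DockThor	A	F108	π-π
NATx	NAT28-416626	DockThor	A	K110	HB
NATx	NAT28-416626	DockThor	A	F293	HD
NATx	NAT28-416626	DockThor	A	Y295	π-π
NATx	NAT28-416626	DockThor	A	K297	π-C
NATx	NAT28-416626	DockThor	A	I310	HD
NATx	NAT28-416626	DockThor	B	Y298	HD
NATx	NAT28-416626	DockThor	C	P96	HD
NATx	NAT14-350419	GOLD	A	F88	HD
NATx	NAT14-350419	GOLD	A	F95	HD
NATx	NAT14-350419	GOLD	A	M105	HD
NATx	NAT14-350419	GOLD	A	Y295	HB
NATx	NAT14-350419	GOLD	A	K297	π -C
NATx	NAT14-350419	GOLD	A	I310	HD
NATx	NAT14-350419	GOLD	B	F95	HD
NATx	NAT14-350419	GOLD	B	W167	HD
NATx	NAT14-350419	GOLD	B	Y295	HD
NATx	NAT14-350419	GOLD	B	Y298	HD
NATx	NAT14-350419	DockThor	A	F88	HD
NATx	NAT14-350419	DockThor	A	F95	HD
NATx	NAT14-350419	DockThor	A	F103	HD
NATx	NAT14-350419	DockThor	A	F108	HD
NATx	NAT14-350419	DockThor	A	K110	HD
NATx	NAT14-350419	DockThor	A	F293	HD
NATx	NAT14-350419	DockThor	A	Y295	HD
NATx	NAT14-350419	DockThor	A	K297	π-C
NATx	NAT14-350419	DockThor	A	I310	HD
NATx	NAT14-350419	DockThor	B	Y295	HD
NATx	NAT14-350419	DockThor	B	Y298	HD, HB
NATx	NAT14-350419	DockThor	C	P96	HD
NATx	NAT13-340161	GOLD	A	F88	HD
NATx	NAT13-340161	GOLD	A	F95	HD
NATx	NAT13-340161	GOLD	A	F103	HD
NATx	NAT13-340161	GOLD	A	Y291	HB
NATx	NAT13-340161	GOLD	A	F293	HD
NATx	NAT13-340161	GOLD	A	Y295	HD
NATx	NAT13-340161	GOLD	A	K297	HB
NATx	NAT13-340161	GOLD	B	W167	HD
NATx	NAT13-340161	GOLD	B	Y298	HB
NATx	NAT13-340161	GOLD	C	Q98	HB
NATx	NAT13-340161	DockThor	A	F88	HD
NATx	NAT13-340161	DockThor	A	D92	HD
NATx	NAT13-340161	DockThor	A	F95	HD
NATx	NAT13-340161	DockThor	A	F103	HD
NATx	NAT13-340161	DockThor	A	K110	HB
NATx	NAT13-340161	DockThor	A	F293	HD
NATx	NAT13-340161	DockThor	A	Y295	HB
NATx	NAT13-340161	DockThor	A	K297	HB
NATx	NAT13-340161	DockThor	A	I310	HD
NATx	NAT13-340161	DockThor	B	Y293	HD
NATx	NAT13-340161	DockThor	B	Y298	HB
NATx	NAT13-340161	DockThor	C	P96	HD
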