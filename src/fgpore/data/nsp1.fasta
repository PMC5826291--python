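>Nsp1 S. cerevisiae Nsp1 FG-domain construct (1-601 domain with His/TEV leader, C-terminal Cys anchor)
MSKHHHHSGHHHTGHHHHSGSHHHTGENLYFQGSNFNTPQQNKTPFSFGTANNNSNTTNQ
NSSTGAGAFGTGQSTFGFNNSAPNNTNNANSSITPAFGSNNTGNTAFGNSNPTSNVFGSN
NSTTNTFGSNSAGTSLFGSSSAQQTKSNGTAGGNTFGSSSLFNNSTNSNTTKPAFGGLNF
GGGNNTTPSSTGNANTSNNLFGATANANKPAFSFGATTNDDKKTEPDKPAFSFNSSVGNK
TDAQAPTTGFSFGSQLGGNKTVNEAAKPSLSFGSGSAGANPAGASQPEPTTNEPAKPALS
FGTATSDNKTTNTTPSFSFGAKSDENKAGATSKPAFSFGAKPEEKKDDNSSKPAFSFGAK
SNEDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAFSFGAKPDE
NKASATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSNEDKQDGTAKPAFSFGAKPAEKNN
NETSKPAFSFGAKSDEKKDGDASKPAFSFGAKSDEKKDSDSSKPAFSFGTKSNEKKDSGS
SKPAFSFGAKPDEKKNDEVSKPAFSFGAKANEKKESDESKSAFSFGSKPTGKEEGDGAKA
AISFGAKPEEQKSSDTSKPAFTFGAQKDNEKKTETSC
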